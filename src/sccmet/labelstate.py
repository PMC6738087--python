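"""Exact joint label distributions over the tracked atoms of one metabolite.

A :class:`LabelState` stores the probability of every binary labelling pattern
(bitmask over atoms) of a metabolite.  With at most six carbons plus one
nitrogen tracked per metabolite the state space never exceeds 128 patterns, so
everything downstream — mass-isotopologue distributions (MIDs) and positional
(isotopomer) enrichments — is computed exactly, without sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelState"]

_ATOL = 1e-12


@dataclass
class LabelState:
    """Joint distribution over per-atom label vectors of one metabolite.

    Parameters
    ----------
    metabolite : str
        Metabolite identifier.
    atoms : tuple of str
        Ordered tracked atom names (e.g. ``("C1", "C2", "C3", "N1")``).
        Bit ``i`` of a pattern index refers to ``atoms[i]``.
    probs : numpy.ndarray
        Probability of each of the ``2**len(atoms)`` label patterns.
    """

    metabolite: str
    atoms: tuple[str, ...]
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.atoms = tuple(self.atoms)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (2 ** len(self.atoms),):
            raise ValueError(
                f"{self.metabolite}: expected {2 ** len(self.atoms)} "
                f"probabilities, got {self.probs.shape}"
            )
        if np.any(self.probs < -_ATOL):
            raise ValueError(f"{self.metabolite}: negative probability")
        total = float(self.probs.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.metabolite}: probabilities sum to {total}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def unlabelled(cls, metabolite: str, atoms: tuple[str, ...]) -> "LabelState":
        probs = np.zeros(2 ** len(atoms))
        probs[0] = 1.0
        return cls(metabolite, atoms, probs)

    @classmethod
    def source(
        cls,
        metabolite: str,
        atoms: tuple[str, ...],
        labelled_atoms: tuple[str, ...],
        fraction: float,
    ) -> "LabelState":
        """Two-point source pool: fully light, or labelled at `labelled_atoms`."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"source fraction {fraction} outside [0, 1]")
        mask = 0
        for a in labelled_atoms:
            if a not in atoms:
                raise ValueError(f"{metabolite}: unknown source atom {a!r}")
            mask |= 1 << atoms.index(a)
        probs = np.zeros(2 ** len(atoms))
        probs[0] += 1.0 - fraction
        probs[mask] += fraction
        return cls(metabolite, atoms, probs)

    # -- derived quantities -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def mid(self) -> np.ndarray:
        """Marginal distribution of the labelled-atom count (mass shift).

        Returns a vector of length ``n_atoms + 1`` summing to 1; entry ``x``
        is the m+x isotopologue fraction.
        """
        counts = _popcount(np.arange(self.probs.size))
        return np.bincount(counts, weights=self.probs, minlength=self.n_atoms + 1)

    def carbon_mid(self) -> np.ndarray:
        """MID over carbon atoms only (nitrogen label marginalised out)."""
        carbon_bits = [i for i, a in enumerate(self.atoms) if a.startswith("C")]
        sel = np.zeros(self.probs.size, dtype=int)
        for b in carbon_bits:
            sel += (np.arange(self.probs.size) >> b) & 1
        return np.bincount(sel, weights=self.probs, minlength=len(carbon_bits) + 1)

    def positional(self, position: int | str) -> float:
        """Marginal probability that the atom at `position` is labelled.

        `position` is either an atom name (``"C4"``) or a 0-based index into
        :attr:`atoms`.
        """
        if isinstance(position, str):
            if position not in self.atoms:
                raise IndexError(
                    f"{self.metabolite}: no tracked atom {position!r}"
                )
            bit = self.atoms.index(position)
        else:
            if not 0 <= position < self.n_atoms:
                raise IndexError(
                    f"{self.metabolite}: position {position} out of range"
                )
            bit = position
        labelled = (np.arange(self.probs.size) >> bit) & 1
        return float(self.probs[labelled == 1].sum())

    # -- algebra -----------------------------------------------------------

    def scrambled_carbons(self) -> "LabelState":
        """50/50 mixture of the identity and the reversed carbon order.

        Models two-fold rotational symmetry (succinate, fumarate): the MID is
        unchanged but positional information is symmetrised.
        """
        carbon_bits = [i for i, a in enumerate(self.atoms) if a.startswith("C")]
        perm = {b: carbon_bits[len(carbon_bits) - 1 - j]
                for j, b in enumerate(carbon_bits)}
        out = np.zeros_like(self.probs)
        for pattern, p in enumerate(self.probs):
            if p == 0.0:
                continue
            flipped = 0
            for bit in range(self.n_atoms):
                if (pattern >> bit) & 1:
                    flipped |= 1 << perm.get(bit, bit)
            out[pattern] += 0.5 * p
            out[flipped] += 0.5 * p
        return LabelState(self.metabolite, self.atoms, out)

    @staticmethod
    def mixture(states: list["LabelState"], weights: list[float]) -> "LabelState":
        if len(states) != len(weights) or not states:
            raise ValueError("need matching non-empty states and weights")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {sum(weights)}")
        ref = states[0]
        probs = np.zeros_like(ref.probs)
        for s, w in zip(states, weights):
            if s.atoms != ref.atoms:
                raise ValueError("mixture over differing atom sets")
            if w < -_ATOL:
                raise ValueError(f"negative mixture weight {w}")
            probs += max(w, 0.0) * s.probs
        return LabelState(ref.metabolite, ref.atoms, probs)


def _popcount(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    v = x.copy()
    while np.any(v):
        out += v & 1
        v >>= 1
    return out
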