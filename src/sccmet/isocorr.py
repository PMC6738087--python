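"""Natural-abundance correction and enrichment calculations for MIDs.

A GC-MS isotopologue measurement of a metabolite with ``n_c`` tracked carbons
(and optionally one tracked nitrogen, for dual 13C/15N tracers) is a vector of
intensities C(m+0) ... C(m+n).  Naturally occurring 13C and 15N in the
unlabelled atoms smear a molecule with k tracer atoms across observed shifts
j >= k; the correction deconvolves that smearing.  Corrected fractional
abundances feed two readouts:

* per-isotopologue percent enrichment,
      Enrichment(m+x) = C(m+x) / sum_k C(m+k) x 100%,
* whole-molecule percent of carbons enriched,
      13Cmet = sum_x x * f(m+x) / n_c x 100,
  the abundance-weighted mean number of labelled carbons over the skeleton.

Correction is solved as non-negative least squares rather than by matrix
inversion, because inversion turns measurement noise into negative
abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import binom

__all__ = [
    "P13C_NATURAL",
    "P15N_NATURAL",
    "CorrectionMatrix",
    "EnrichmentProfile",
    "EmptySignalError",
    "build_correction_matrix",
    "convolve_mid",
    "correct_mid",
    "percent_enrichment",
    "total_carbon_enrichment",
    "carbon_marginal",
    "quantify_vs_reference",
    "enrich_table",
]

#: IUPAC representative isotopic abundances
P13C_NATURAL = 0.0107
P15N_NATURAL = 0.00364


class EmptySignalError(ValueError):
    """Raised when an all-zero intensity vector reaches a normalising step."""


@dataclass(frozen=True)
class CorrectionMatrix:
    """Lower-triangular map from true labelled counts to observed shifts.

    ``entries[j, k]`` is the probability that a molecule carrying ``k`` tracer
    atoms is observed at nominal mass shift ``j``, due to natural heavy
    isotopes among its remaining unlabelled C and N atoms (independent
    binomials, convolved).  Columns sum to 1 because the observation window
    spans all tracked atoms.
    """

    entries: np.ndarray
    n_c: int
    n_n: int
    p13: float
    p15: float

    @property
    def size(self) -> int:
        return self.entries.shape[0]


def build_correction_matrix(
    n_c: int,
    n_n: int = 0,
    p13: float = P13C_NATURAL,
    p15: float = P15N_NATURAL,
) -> CorrectionMatrix:
    """Natural-abundance correction matrix for ``n_c`` carbons, ``n_n`` nitrogens.

    For column k the tracer atoms are attributed to carbons first (a 13C
    tracer fills carbon positions before a 15N label adds the final shift),
    leaving ``max(n_c - k, 0)`` carbons and ``n_n - max(k - n_c, 0)``
    nitrogens free to carry natural heavy isotopes.
    """
    if n_c < 1 or n_n < 0:
        raise ValueError(f"invalid atom counts: n_c={n_c}, n_n={n_n}")
    if not (0.0 <= p13 < 1.0 and 0.0 <= p15 < 1.0):
        raise ValueError("natural abundances must lie in [0, 1)")
    n = n_c + n_n
    M = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        free_c = max(n_c - k, 0)
        free_n = n_n - max(k - n_c, 0)
        pmf_c = binom.pmf(np.arange(free_c + 1), free_c, p13)
        pmf_n = binom.pmf(np.arange(free_n + 1), free_n, p15)
        extra = np.convolve(pmf_c, pmf_n)
        top = min(n - k, extra.size - 1)
        M[k:k + top + 1, k] = extra[: top + 1]
    return CorrectionMatrix(entries=M, n_c=n_c, n_n=n_n, p13=p13, p15=p15)


def convolve_mid(fractions: np.ndarray, M: CorrectionMatrix) -> np.ndarray:
    """Forward direction: smear true fractions into observed intensities."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size != M.size:
        raise ValueError(
            f"fraction length {fractions.size} != matrix size {M.size}"
        )
    return M.entries @ fractions


def correct_mid(raw: np.ndarray, M: CorrectionMatrix) -> np.ndarray:
    """Deconvolve natural abundance from raw intensities.

    Solves ``M f ~ raw/sum(raw)`` with ``f >= 0`` (NNLS) and renormalises
    ``f`` to sum to one.

    Raises
    ------
    EmptySignalError
        If `raw` is all zero.
    ValueError
        On a dimension mismatch or negative intensities.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size != M.size:
        raise ValueError(f"intensity length {raw.size} != matrix size {M.size}")
    if np.any(raw < 0):
        raise ValueError("raw intensities must be non-negative")
    total = raw.sum()
    if total == 0:
        raise EmptySignalError("all-zero isotopologue intensities")
    f, _ = nnls(M.entries, raw / total)
    s = f.sum()
    if s == 0:  # pragma: no cover - NNLS of a positive signal is positive
        raise EmptySignalError("correction produced an empty signal")
    return f / s


def percent_enrichment(fractions: np.ndarray) -> np.ndarray:
    """Per-isotopologue percentages, C(m+x)/sum_k C(m+k) x 100."""
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0):
        raise ValueError("fractions must be non-negative")
    total = fractions.sum()
    if total == 0:
        raise EmptySignalError("all-zero fractions")
    return fractions / total * 100.0


def total_carbon_enrichment(fractions: np.ndarray, n_c: int) -> float:
    """Percent of skeleton carbons enriched: sum_x x f(m+x) / n_c x 100.

    `fractions` must index carbon mass shifts only (marginalise dual-tracer
    vectors with :func:`carbon_marginal` first).
    """
    if n_c < 1:
        raise ValueError("n_c must be >= 1")
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size > n_c + 1:
        raise ValueError(
            f"{fractions.size - 1} carbon shifts but only {n_c} carbons; "
            "marginalise nitrogen shifts first"
        )
    f = fractions / fractions.sum() if fractions.sum() else None
    if f is None:
        raise EmptySignalError("all-zero fractions")
    return float(np.arange(f.size) @ f / n_c * 100.0)


def carbon_marginal(fractions: np.ndarray, n_c: int, n_n: int) -> np.ndarray:
    """Collapse a nominal-mass-shift MID to carbon-only shifts.

    Shifts beyond ``n_c`` can only arise from the nitrogen label, so their
    mass is attributed to ``n_c`` carbons plus nitrogen; shifts within the
    carbon range are attributed to carbon.  Exact attribution for mixed
    patterns requires the joint label state (see
    :meth:`sccmet.labelstate.LabelState.carbon_mid`); this marginalisation is
    the measurement-side approximation used when only the MID is available.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size != n_c + n_n + 1:
        raise ValueError("fraction length inconsistent with atom counts")
    if n_n == 0:
        return fractions.copy()
    out = fractions[: n_c + 1].copy()
    out[n_c] += fractions[n_c + 1:].sum()
    return out


def quantify_vs_reference(
    peak_area: float,
    ref_area: float,
    ref_amount_nmol: float,
    protein_mg: float,
) -> float:
    """Concentration in nmol per mg protein against an internal standard.

    Mirrors quantification against a spiked reference (norleucine for GC-MS,
    DSS for NMR): amount = peak/ref x ref_nmol, then divided by mg protein.
    """
    if ref_area <= 0 or ref_amount_nmol <= 0 or protein_mg <= 0:
        raise ValueError("reference area/amount and protein mass must be > 0")
    if peak_area < 0:
        raise ValueError("peak area must be non-negative")
    return peak_area / ref_area * ref_amount_nmol / protein_mg


@dataclass(frozen=True)
class EnrichmentProfile:
    """Corrected enrichment readouts of one metabolite in one sample."""

    fractions: np.ndarray       # corrected, sums to 1
    percent: np.ndarray         # per-isotopologue %, sums to 100
    carbon_percent: float       # whole-molecule % carbons enriched
    n_c: int
    n_n: int

    @classmethod
    def from_raw(
        cls,
        raw: np.ndarray,
        n_c: int,
        n_n: int = 0,
        p13: float = P13C_NATURAL,
        p15: float = P15N_NATURAL,
    ) -> "EnrichmentProfile":
        M = build_correction_matrix(n_c, n_n, p13, p15)
        fractions = correct_mid(np.asarray(raw, dtype=float), M)
        return cls.from_fractions(fractions, n_c, n_n)

    @classmethod
    def from_fractions(
        cls, fractions: np.ndarray, n_c: int, n_n: int = 0
    ) -> "EnrichmentProfile":
        fractions = np.asarray(fractions, dtype=float)
        pct = percent_enrichment(fractions)
        carbon = total_carbon_enrichment(
            carbon_marginal(fractions, n_c, n_n), n_c
        )
        return cls(fractions=fractions, percent=pct, carbon_percent=carbon,
                   n_c=n_c, n_n=n_n)


def enrich_table(
    df: pd.DataFrame,
    p13: float = P13C_NATURAL,
    p15: float = P15N_NATURAL,
    correct: bool = True,
) -> pd.DataFrame:
    """Correct and enrich a long-format isotopologue table.

    `df` must carry columns ``sample_id, subject_id, tissue, tracer,
    metabolite, n_c, n_n, mass_shift, intensity``.  Returns the same keys plus
    ``fraction``, ``percent`` and ``carbon_percent`` per isotopologue row.
    Set ``correct=False`` to skip natural-abundance deconvolution (e.g. for
    positional NMR data that are passed through uncorrected).
    """
    required = {"sample_id", "subject_id", "tissue", "tracer", "metabolite",
                "n_c", "n_n", "mass_shift", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"isotopologue table missing columns {sorted(missing)}")
    out = []
    keys = ["sample_id", "subject_id", "tissue", "tracer", "metabolite"]
    for key_vals, grp in df.groupby(keys, sort=True):
        n_c = int(grp["n_c"].iloc[0])
        n_n = int(grp["n_n"].iloc[0])
        vec = np.zeros(n_c + n_n + 1)
        shifts = grp["mass_shift"].to_numpy(dtype=int)
        if shifts.min() < 0 or shifts.max() > n_c + n_n:
            raise ValueError(
                f"{key_vals}: mass shift outside 0..{n_c + n_n}"
            )
        vec[shifts] = grp["intensity"].to_numpy(dtype=float)
        if correct:
            prof = EnrichmentProfile.from_raw(vec, n_c, n_n, p13, p15)
        else:
            prof = EnrichmentProfile.from_fractions(vec / vec.sum(), n_c, n_n)
        for shift in range(n_c + n_n + 1):
            rec = dict(zip(keys, key_vals))
            rec.update(
                n_c=n_c, n_n=n_n, mass_shift=shift,
                fraction=prof.fractions[shift],
                percent=prof.percent[shift],
                carbon_percent=prof.carbon_percent,
            )
            out.append(rec)
    return pd.DataFrame(out)
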