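"""Monte-Carlo molecule simulator — an independent cross-check of propagation.

Instead of manipulating probability tables, this module draws individual
molecules: each product molecule picks a route at random (by the mixture
weights), recursively draws fresh substrate molecules, copies atom labels along
the route's atom map, flips pool atoms as independent Bernoulli draws, and
applies the 50/50 symmetry coin for symmetric metabolites.  Substrate draws
are fresh per product molecule, so the sampler shares no code path, and no
distributional shortcut, with :func:`sccmet.tracer.propagate`.
"""

from __future__ import annotations

import numpy as np

from .network import AtomMap, PathwayParams, builtin_atom_map, eval_weight

__all__ = ["sample_mid", "sample_masks"]


def sample_masks(
    metabolite: str,
    n: int,
    tracer: str,
    params: PathwayParams,
    rng: np.random.Generator,
    network: AtomMap | None = None,
) -> np.ndarray:
    """Draw `n` molecules of `metabolite`; return label bitmasks (uint32).

    Bit ``i`` corresponds to atom ``i`` of the network's atom order for that
    metabolite (carbons first, then nitrogen).
    """
    network = network or builtin_atom_map()
    network.validate(tracer)
    network.check_weights(tracer, params)
    pools = network.source_pools(tracer)
    routes_by_product: dict[str, list] = {}
    for r in network.routes_for(tracer):
        routes_by_product.setdefault(r.product, []).append(r)

    def draw(met: str, m: int) -> np.ndarray:
        atoms = network.atoms_of(met)
        if met in pools:
            frac_param, labelled = pools[met]
            mask = 0
            for a in labelled:
                mask |= 1 << atoms.index(a)
            hot = rng.random(m) < params.get(frac_param)
            out = np.where(hot, np.uint32(mask), np.uint32(0)).astype(np.uint32)
        else:
            routes = routes_by_product[met]
            weights = np.array([eval_weight(r.weight, params) for r in routes])
            choice = rng.choice(len(routes), size=m, p=weights)
            out = np.zeros(m, dtype=np.uint32)
            for ri, route in enumerate(routes):
                idx = np.flatnonzero(choice == ri)
                if idx.size == 0:
                    continue
                sub_masks = {s: draw(s, idx.size) for s in route.substrates()}
                part = np.zeros(idx.size, dtype=np.uint32)
                for atom, src in route.atom_sources.items():
                    dst_bit = atoms.index(atom)
                    if src[0] == "met":
                        _, sub, sub_atom = src
                        src_bit = network.atoms_of(sub).index(sub_atom)
                        part |= (
                            (sub_masks[sub] >> np.uint32(src_bit)) & np.uint32(1)
                        ) << np.uint32(dst_bit)
                    elif src[0] == "pool":
                        hot = rng.random(idx.size) < params.get(src[1])
                        part |= hot.astype(np.uint32) << np.uint32(dst_bit)
                out[idx] = part
        if met in network.symmetric:
            out = _scramble(out, atoms, rng)
        return out

    return draw(metabolite, n)


def _scramble(masks: np.ndarray, atoms: tuple[str, ...],
              rng: np.random.Generator) -> np.ndarray:
    carbon_bits = [i for i, a in enumerate(atoms) if a.startswith("C")]
    reversed_masks = np.zeros_like(masks)
    for j, b in enumerate(carbon_bits):
        dst = carbon_bits[len(carbon_bits) - 1 - j]
        reversed_masks |= (
            (masks >> np.uint32(b)) & np.uint32(1)
        ) << np.uint32(dst)
    for i, a in enumerate(atoms):
        if not a.startswith("C"):
            reversed_masks |= masks & np.uint32(1 << i)
    coin = rng.random(masks.size) < 0.5
    return np.where(coin, reversed_masks, masks).astype(np.uint32)


def sample_mid(
    metabolite: str,
    n: int,
    tracer: str,
    params: PathwayParams,
    rng: np.random.Generator,
    network: AtomMap | None = None,
) -> np.ndarray:
    """Empirical MID (labelled-atom-count distribution) from `n` molecules."""
    network = network or builtin_atom_map()
    masks = sample_masks(metabolite, n, tracer, params, rng, network)
    n_atoms = len(network.atoms_of(metabolite))
    counts = np.zeros(masks.size, dtype=np.int64)
    v = masks.astype(np.int64)
    while np.any(v):
        counts += v & 1
        v >>= 1
    return np.bincount(counts, minlength=n_atoms + 1) / n
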