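"""Atom-transition networks: schema, validation and the built-in core map.

An :class:`AtomMap` is a list of mixing routes between metabolites, each route
assigning every product atom to exactly one substrate atom, an unlabelled
source, or a scalar labelled pool (e.g. CO2).  Route weights are mixing
fractions — numbers, parameter names, or ``"1-<parameter>"`` — and the routes
of a product must sum to one.  The built-in network (``networks/core.yaml``)
covers glycolysis to lactate, serine/glycine biosynthesis with SHMT exchange,
the oxidative pentose phosphate branch, PDH and pyruvate carboxylation, one
oxidative Krebs span, oxidative vs reductive glutamine entry into citrate, GOT
transamination to aspartate, and glutathione glutamyl incorporation.
"""

from __future__ import annotations

import graphlib
import importlib.resources
import re
from dataclasses import dataclass, field, fields as dc_fields

import yaml

__all__ = [
    "TRACERS",
    "MEASURED_METABOLITES",
    "PathwayParams",
    "Route",
    "AtomMap",
    "NetworkError",
    "load_atom_map",
    "builtin_atom_map",
]

TRACERS = ("U13C-glucose", "U13C-glutamine", "U13C-U15N-glutamine")

#: metabolites reported by the forward model (the pools a GC-MS/NMR assay reads)
MEASURED_METABOLITES = (
    "lactate", "serine", "glycine", "ribose", "citrate", "glutamate",
    "fumarate", "malate", "aspartate", "gsh_glutamyl",
)


class NetworkError(ValueError):
    """Raised for invalid atom maps (unmapped atoms, cycles, bad weights)."""


@dataclass(frozen=True)
class PathwayParams:
    """Mixing fractions of the built-in network, all in [0, 1].

    Attributes
    ----------
    f_glc, f_gln : float
        Labelled fractions of the glucose and glutamine source pools.
    f_pdh : float
        Fraction of acetyl-CoA made from pyruvate (PDH flux share).
    f_pc : float
        Fraction of citrate-synthase oxaloacetate from pyruvate carboxylation.
    f_ox : float
        Fraction of citrate made oxidatively (OAA + acetyl-CoA); the
        complement ``f_red = 1 - f_ox`` is the reductive-carboxylation share.
    f_ser : float
        Fraction of the serine pool made de novo from 3-phosphoglycerate.
    e_shmt : float
        Extent of the SHMT serine/glycine exchange (hydroxymethyl swap).
    t_got : float
        Fraction of aspartate amino-N transaminated from glutamate (GOT).
    t_psat : float
        Fraction of de-novo serine amino-N drawn from glutamate (PSAT).
    f_gsh : float
        Fraction of the glutathione glutamyl moiety from the glutamate pool.
    f_acl : float
        Fraction of the readout oxaloacetate/malate pool returned by
        ATP-citrate lyase cleavage of citrate.
    p_co2 : float
        Labelled fraction of the CO2 pool (default: unlabelled).
    """

    f_glc: float = 0.8
    f_gln: float = 0.8
    f_pdh: float = 0.6
    f_pc: float = 0.1
    f_ox: float = 0.8
    f_ser: float = 0.4
    e_shmt: float = 0.3
    t_got: float = 0.8
    t_psat: float = 0.9
    f_gsh: float = 0.5
    f_acl: float = 0.0
    p_co2: float = 0.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} = {v} outside [0, 1]")

    @property
    def f_red(self) -> float:
        """Reductive-carboxylation fraction, ``1 - f_ox``."""
        return 1.0 - self.f_ox

    def replace(self, **updates: float) -> "PathwayParams":
        """Return a copy with updated fractions; accepts the alias ``f_red``."""
        if "f_red" in updates:
            if "f_ox" in updates:
                raise ValueError("give f_red or f_ox, not both")
            updates["f_ox"] = 1.0 - updates.pop("f_red")
        current = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        unknown = set(updates) - set(current)
        if unknown:
            raise ValueError(f"unknown pathway parameters: {sorted(unknown)}")
        current.update(updates)
        return PathwayParams(**current)

    def get(self, name: str) -> float:
        if name == "f_red":
            return self.f_red
        return getattr(self, name)


_NUMBER = re.compile(r"^-?\d+(\.\d+)?$")


def eval_weight(expr: str | float | int, params: PathwayParams) -> float:
    """Evaluate a route-weight expression: number, param, or ``1-param``."""
    if isinstance(expr, (int, float)):
        return float(expr)
    expr = expr.strip()
    if _NUMBER.match(expr):
        return float(expr)
    if expr.startswith("1-"):
        return 1.0 - params.get(expr[2:].strip())
    return params.get(expr)


@dataclass(frozen=True)
class Route:
    """One mixing route into a product metabolite."""

    product: str
    weight: str | float
    #: product atom -> ("met", metabolite, atom) | ("pool", param) | ("unlabelled",)
    atom_sources: dict[str, tuple]
    tracers: tuple[str, ...] | None = None  # None = all tracers

    def substrates(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(
            src[1] for src in self.atom_sources.values() if src[0] == "met"
        ))


@dataclass
class AtomMap:
    """A validated atom-transition network."""

    metabolites: dict[str, tuple[str, ...]]        # name -> atom names
    symmetric: set[str] = field(default_factory=set)
    sources: dict[str, dict] = field(default_factory=dict)  # tracer -> pools
    routes: list[Route] = field(default_factory=list)

    def atoms_of(self, met: str) -> tuple[str, ...]:
        try:
            return self.metabolites[met]
        except KeyError:
            raise NetworkError(f"unknown metabolite {met!r}") from None

    def routes_for(self, tracer: str) -> list[Route]:
        return [r for r in self.routes
                if r.tracers is None or tracer in r.tracers]

    def source_pools(self, tracer: str) -> dict[str, tuple[str, tuple[str, ...]]]:
        if tracer not in self.sources:
            raise NetworkError(
                f"tracer {tracer!r} not defined; choose from {sorted(self.sources)}"
            )
        return {
            met: (cfg["fraction"], tuple(cfg["labelled_atoms"]))
            for met, cfg in self.sources[tracer].items()
        }

    # -- validation --------------------------------------------------------

    def validate(self, tracer: str) -> list[str]:
        """Check structural soundness for one tracer; return evaluation order.

        Raises :class:`NetworkError` on unmapped atoms, out-of-range atom
        references, missing routes, or cycles.
        """
        routes = self.routes_for(tracer)
        srcs = set(self.source_pools(tracer))
        by_product: dict[str, list[Route]] = {}
        for r in routes:
            by_product.setdefault(r.product, []).append(r)

        for r in routes:
            atoms = self.atoms_of(r.product)
            mapped = set(r.atom_sources)
            if mapped != set(atoms):
                missing = set(atoms) - mapped
                extra = mapped - set(atoms)
                raise NetworkError(
                    f"route into {r.product!r}: unmapped atoms {sorted(missing)}"
                    + (f", unknown atoms {sorted(extra)}" if extra else "")
                )
            for atom, src in r.atom_sources.items():
                if src[0] == "met":
                    _, sub, sub_atom = src
                    if sub_atom not in self.atoms_of(sub):
                        raise NetworkError(
                            f"route into {r.product!r}: {sub}.{sub_atom} "
                            "does not exist"
                        )

        for met in self.metabolites:
            if met not in srcs and met not in by_product:
                raise NetworkError(
                    f"metabolite {met!r} has no route and is not a "
                    f"{tracer} source"
                )

        deps = {
            product: {s for r in rs for s in r.substrates()}
            for product, rs in by_product.items()
        }
        for met in srcs:
            deps.setdefault(met, set())
        try:
            order = list(graphlib.TopologicalSorter(deps).static_order())
        except graphlib.CycleError as exc:
            raise NetworkError(f"cycle in atom map: {exc.args[1]}") from None
        return order

    def check_weights(self, tracer: str, params: PathwayParams) -> None:
        totals: dict[str, float] = {}
        for r in self.routes_for(tracer):
            totals[r.product] = totals.get(r.product, 0.0) + eval_weight(
                r.weight, params
            )
        bad = {m: t for m, t in totals.items() if abs(t - 1.0) > 1e-9}
        if bad:
            raise NetworkError(f"route weights do not sum to 1: {bad}")


def _parse_atom_source(spec: str) -> tuple:
    spec = str(spec).strip()
    if spec == "unlabelled":
        return ("unlabelled",)
    if spec.startswith("pool."):
        return ("pool", spec[5:])
    if "." not in spec:
        raise NetworkError(f"bad atom source {spec!r}")
    met, atom = spec.rsplit(".", 1)
    return ("met", met, atom)


def load_atom_map(text_or_path) -> AtomMap:
    """Parse an atom map from YAML text or a file path."""
    if hasattr(text_or_path, "read"):
        doc = yaml.safe_load(text_or_path)
    else:
        text = str(text_or_path)
        if "\n" not in text and text.endswith((".yaml", ".yml")):
            with open(text, encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)

    metabolites: dict[str, tuple[str, ...]] = {}
    symmetric: set[str] = set()
    for name, cfg in doc["metabolites"].items():
        n_c = int(cfg.get("carbons", 0))
        n_n = int(cfg.get("nitrogens", 0))
        if n_c < 0 or n_n < 0 or n_c + n_n == 0:
            raise NetworkError(f"{name}: invalid atom counts ({n_c} C, {n_n} N)")
        atoms = tuple(f"C{i + 1}" for i in range(n_c)) + tuple(
            f"N{i + 1}" for i in range(n_n)
        )
        metabolites[name] = atoms
        if cfg.get("symmetric", False):
            symmetric.add(name)

    routes = [
        Route(
            product=r["product"],
            weight=r["weight"],
            atom_sources={a: _parse_atom_source(s) for a, s in r["atoms"].items()},
            tracers=tuple(r["tracers"]) if "tracers" in r else None,
        )
        for r in doc["routes"]
    ]
    amap = AtomMap(
        metabolites=metabolites,
        symmetric=symmetric,
        sources=doc.get("sources", {}),
        routes=routes,
    )
    for tracer in amap.sources:
        amap.validate(tracer)
    return amap


_BUILTIN: AtomMap | None = None


def builtin_atom_map() -> AtomMap:
    """The shipped core network (parsed once, cached)."""
    global _BUILTIN
    if _BUILTIN is None:
        ref = importlib.resources.files("sccmet") / "networks" / "core.yaml"
        _BUILTIN = load_atom_map(ref.read_text(encoding="utf-8"))
    return _BUILTIN
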