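"""Synthetic cohorts and tracer experiments with known planted structure.

The expression generator emulates a three-group lung cohort (NC / AdC / SCC,
default sizes 65/45/27) with log2-normal intensities, a planted set of
SCC-overexpressed signature genes (default: the 24 metabolic enzymes from
ALDOC to ASNS) and a co-elevated Notch-target block.  The tracer generator
emulates paired tumour/NC tissue-slice experiments: true corrected MIDs come
from exact label propagation through the built-in atom map, are smeared with
natural 13C/15N abundance, scaled by a per-subject random intercept, and
perturbed with multiplicative log-normal noise.  Every generator is
deterministic under its seed and retains its ground truth for assertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isocorr import P13C_NATURAL, P15N_NATURAL, build_correction_matrix, convolve_mid
from .network import MEASURED_METABOLITES, PathwayParams, TRACERS, builtin_atom_map
from .notch import DEFAULT_TARGETS
from .signature import ExpressionCohort, PROCESS_CLASSES
from .tracer import propagate

__all__ = [
    "SIGNATURE_GENES_24",
    "CohortSpec",
    "TracerSpec",
    "TracerDataset",
    "generate_expression_cohort",
    "generate_annotation",
    "generate_tracer_dataset",
]

#: default planted signature: the 24 SCC-distinguishing metabolic enzymes
SIGNATURE_GENES_24 = (
    "ALDOC", "GAPDH", "TPI1", "PGAM1",            # glycolysis
    "G6PD", "TALDO1",                              # pentose phosphate pathway
    "CTPS1", "GMPS", "UMPS", "PAICS",              # nucleotide biosynthesis
    "PSAT1", "SHMT2", "MTHFD2", "AHCY",            # serine / one-carbon
    "GCLM", "GGH", "GSS",                          # glutathione
    "GOT2", "IDH2", "MDH2", "ME1",                 # malate-aspartate / Krebs
    "CKMT1", "BDH1", "ASNS",                       # creatine/butyrate/Asn
)


class ConfigurationError(ValueError):
    """Raised for invalid generator specifications."""


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic expression cohort.

    Defaults mirror a 65 NC / 45 AdC / 27 SCC cohort with the 24-gene
    signature planted one log2 unit up in SCC, the five Notch targets
    likewise, per-gene log2 noise SD 0.4, and no gene-gene correlation
    (an optional equicorrelated Notch block is available via
    `notch_block_corr`).
    """

    n_nc: int = 65
    n_adc: int = 45
    n_scc: int = 27
    n_genes: int = 360
    signature_genes: tuple[str, ...] = SIGNATURE_GENES_24
    notch_targets: tuple[str, ...] = DEFAULT_TARGETS
    scc_log2fc: float = 1.0
    notch_log2fc: float = 1.0
    noise_sd: float = 0.4
    notch_block_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_nc, self.n_adc, self.n_scc) < 0:
            raise ConfigurationError("sample counts must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0.0 <= self.notch_block_corr < 1.0:
            raise ConfigurationError("notch_block_corr must lie in [0, 1)")
        planted = set(self.signature_genes) | set(self.notch_targets)
        if set(self.signature_genes) & set(self.notch_targets):
            raise ConfigurationError(
                "signature genes and Notch targets must be disjoint"
            )
        if len(planted) > self.n_genes:
            raise ConfigurationError("planted genes exceed the gene universe")

    @property
    def gene_universe(self) -> list[str]:
        n_fill = self.n_genes - len(self.signature_genes) - len(self.notch_targets)
        filler = [f"MG{i + 1:04d}" for i in range(n_fill)]
        return list(self.signature_genes) + list(self.notch_targets) + filler


def generate_expression_cohort(spec: CohortSpec) -> ExpressionCohort:
    """Draw a cohort: log2-normal baseline + planted SCC shifts + noise."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_universe
    n_samples = spec.n_nc + spec.n_adc + spec.n_scc
    tissue = (["NC"] * spec.n_nc + ["AdC"] * spec.n_adc + ["SCC"] * spec.n_scc)
    samples = [f"{t}{i + 1:03d}" for i, t in enumerate(tissue)]

    baseline = rng.uniform(6.0, 12.0, size=len(genes))
    log2 = np.tile(baseline[:, None], (1, n_samples))

    scc_cols = np.array([t == "SCC" for t in tissue])
    sig_rows = [genes.index(g) for g in spec.signature_genes]
    notch_rows = [genes.index(g) for g in spec.notch_targets]
    log2[np.ix_(sig_rows, np.flatnonzero(scc_cols))] += spec.scc_log2fc
    log2[np.ix_(notch_rows, np.flatnonzero(scc_cols))] += spec.notch_log2fc

    noise = rng.standard_normal((len(genes), n_samples)) * spec.noise_sd
    if spec.notch_block_corr > 0 and notch_rows:
        # equicorrelated block: shared factor + independent residual
        rho = spec.notch_block_corr
        shared = rng.standard_normal(n_samples)
        block = (np.sqrt(rho) * shared[None, :]
                 + np.sqrt(1 - rho)
                 * rng.standard_normal((len(notch_rows), n_samples)))
        noise[notch_rows, :] = block * spec.noise_sd
    log2 += noise

    matrix = pd.DataFrame(2.0 ** log2, index=genes, columns=samples)
    metadata = pd.DataFrame(
        {"tissue": tissue, "subject_id": samples}, index=pd.Index(samples, name="sample_id")
    )
    return ExpressionCohort(matrix=matrix, metadata=metadata)


def generate_annotation(spec: CohortSpec, frac_noncatalytic: float = 0.1
                        ) -> pd.DataFrame:
    """Annotation table for the cohort's gene universe.

    Planted genes are always catalytic with a metabolic class; a fraction of
    filler genes is marked non-catalytic or classless so the enzyme filter
    has something to remove.  Deterministic under the cohort seed.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = spec.gene_universe
    planted = set(spec.signature_genes) | set(spec.notch_targets)
    classes_pool = sorted(PROCESS_CLASSES)
    records = []
    for g in genes:
        if g in planted:
            catalytic, classes = 1, {rng.choice(classes_pool)}
        else:
            u = rng.random()
            if u < frac_noncatalytic / 2:
                catalytic, classes = 0, {rng.choice(classes_pool)}
            elif u < frac_noncatalytic:
                catalytic, classes = 1, set()
            else:
                catalytic, classes = 1, {rng.choice(classes_pool)}
        records.append({
            "gene_id": g, "catalytic": catalytic,
            "classes": ";".join(sorted(classes)),
        })
    return pd.DataFrame(records).set_index("gene_id")


# ---------------------------------------------------------------------------
# tracer experiments
# ---------------------------------------------------------------------------

def _default_tissue_params() -> dict[str, PathwayParams]:
    """Planted pathway usage: tumours run more reductive carboxylation,
    de-novo serine synthesis and glutathione turnover than NC lung."""
    nc = PathwayParams(f_ox=0.9, f_ser=0.3, f_gsh=0.4, f_pdh=0.5)
    tumour = PathwayParams(f_ox=0.7, f_ser=0.5, f_gsh=0.6, f_pdh=0.7)
    return {"NC": nc, "AdC": nc.replace(f_ox=0.85), "SCC": tumour}


@dataclass(frozen=True)
class TracerSpec:
    """Study conditions of a paired tumour/NC tracer experiment."""

    tracer: str = "U13C-glutamine"
    n_subjects: int = 10
    path_params: dict[str, PathwayParams] | PathwayParams = field(
        default_factory=_default_tissue_params
    )
    histotypes: tuple[str, ...] = ("AdC", "SCC")
    metabolites: tuple[str, ...] = MEASURED_METABOLITES
    noise_cv: float = 0.05
    subject_sd: float = 0.2        # per-subject log2 intensity intercept
    base_intensity: float = 1.0e6
    natural_abundance: bool = True
    p13: float = P13C_NATURAL
    p15: float = P15N_NATURAL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tracer not in TRACERS:
            raise ConfigurationError(
                f"unknown tracer {self.tracer!r}; choose from {TRACERS}"
            )
        if self.noise_cv < 0 or self.subject_sd < 0:
            raise ConfigurationError("noise_cv and subject_sd must be >= 0")
        if self.n_subjects < 1:
            raise ConfigurationError("need at least one subject")
        net = builtin_atom_map()
        for m in self.metabolites:
            net.atoms_of(m)

    def params_for(self, tissue: str) -> PathwayParams:
        if isinstance(self.path_params, PathwayParams):
            return self.path_params
        try:
            return self.path_params[tissue]
        except KeyError:
            raise ConfigurationError(
                f"no pathway parameters for tissue {tissue!r}"
            ) from None


@dataclass
class TracerDataset:
    """Generated isotopologue table plus its ground truth."""

    table: pd.DataFrame
    true_mids: dict[str, dict[str, np.ndarray]]   # tissue -> metabolite -> MID
    spec: TracerSpec


def generate_tracer_dataset(spec: TracerSpec) -> TracerDataset:
    """Simulate paired tumour/NC isotopologue intensities.

    For every subject of every histotype, both the tumour and its paired NC
    tissue are measured for each metabolite: true MID from exact propagation,
    optional natural-abundance convolution, a shared per-subject intensity
    intercept (log2 SD `subject_sd`), and multiplicative log-normal noise
    with coefficient of variation `noise_cv` on each isotopologue intensity.
    """
    rng = np.random.default_rng(spec.seed)
    net = builtin_atom_map()

    tissues_needed = sorted({"NC", *spec.histotypes})
    true_mids: dict[str, dict[str, np.ndarray]] = {}
    for tissue in tissues_needed:
        states = propagate(net, spec.tracer, spec.params_for(tissue))
        true_mids[tissue] = {m: states[m].mid() for m in spec.metabolites}

    sigma = (np.sqrt(np.log1p(spec.noise_cv ** 2)) if spec.noise_cv > 0
             else 0.0)
    rows = []
    for histotype in spec.histotypes:
        for s in range(spec.n_subjects):
            subject = f"{histotype}-P{s + 1:02d}"
            intercept = 2.0 ** (rng.normal(0.0, spec.subject_sd))
            for tissue in ("NC", histotype):
                sample = f"{subject}-{tissue}"
                for met in spec.metabolites:
                    atoms = net.atoms_of(met)
                    n_c = sum(a.startswith("C") for a in atoms)
                    n_n = len(atoms) - n_c
                    mid = true_mids[tissue][met]
                    if spec.natural_abundance:
                        M = build_correction_matrix(n_c, n_n, spec.p13, spec.p15)
                        expected = convolve_mid(mid, M)
                    else:
                        expected = mid
                    scale = spec.base_intensity * intercept
                    if sigma > 0:
                        noise = np.exp(
                            rng.normal(-sigma ** 2 / 2, sigma,
                                       size=expected.size)
                        )
                    else:
                        noise = np.ones(expected.size)
                    intensity = scale * expected * noise
                    for shift, val in enumerate(intensity):
                        rows.append({
                            "sample_id": sample, "subject_id": subject,
                            "tissue": tissue, "tracer": spec.tracer,
                            "metabolite": met, "n_c": n_c, "n_n": n_n,
                            "mass_shift": shift, "intensity": val,
                        })
    return TracerDataset(table=pd.DataFrame(rows), true_mids=true_mids,
                         spec=spec)
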