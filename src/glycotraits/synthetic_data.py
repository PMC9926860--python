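"""Synthetic AML-like cohorts with fully known ground truth.

The generator emulates the statistical structure of the real meta-omics
setting without any external data:

* **Compositional glycomics** — per glycan class (N, O, GSL) a library of
  condensed-IUPAC template structures with hand-annotated epitope counts;
  per-sample relative abundances are Dirichlet-distributed around
  group-specific target compositions and always total 100 within a class.
* **FAB group shifts** — samples carry FAB labels; "M5"-like samples are
  up-shifted on (s)Le^x/a-bearing glycans and "M6"-like samples on
  (non-Lewis) sialylated glycans, reproducing the monocytic-vs-erythroid
  contrast the pipeline is meant to detect.
* **Monotone expression couplings** — each coupled glycosyltransferase (GST)
  is a monotone function of a derived trait plus Gaussian noise, and each
  coupled transcription factor (TF) drives a combination of GST signals, so
  trait↔GST and TF↔GST correlation signs are known by construction.

Ground truth (exact trait values computed by plain nested-loop accumulation
from the planted counts, every coupling sign, every group shift) is returned
alongside the data, so every downstream stage of the pipeline can be tested
for recovery.  With ``dirichlet_concentration=None`` and
``expression_noise_sd=0`` the cohort is noise-free and recovery is exact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .glycan_model import parse_glycan
from .trait_engine import GlycanRecord, GlycomicsPanel, TraitMatrix, integrate_traits
from .omics_io import (
    ExpressionMatrix,
    GenePanel,
    attach_panels,
    write_expression_matrix,
    write_glycomics_table,
    write_manifest,
)

__all__ = [
    "GlycanTemplate",
    "Coupling",
    "SynthConfig",
    "Cohort",
    "GroundTruth",
    "default_templates",
    "generate_cohort",
    "generate_cohort_pair",
    "write_fixture_set",
    "DEFAULT_GST_PANEL",
    "DEFAULT_TF_PANEL",
]


@dataclass(frozen=True)
class GlycanTemplate:
    """A library structure with hand-annotated (planted) epitope counts.

    ``trait_counts`` is the ground truth used to validate the motif engine;
    traits not listed count 0.  ``tags`` drive the FAB group shifts:
    ``slexa`` (carries a Lewis-family epitope), ``sial`` (sialylated but not
    Lewis), ``h`` (blood-group H).
    """

    name: str
    glycan_class: str
    structure: str
    trait_counts: dict[str, float] = field(default_factory=dict)
    tags: frozenset[str] = frozenset()


def default_templates() -> list[GlycanTemplate]:
    """Built-in template library: 8 structures per glycan class."""
    t = GlycanTemplate
    n_core = "Man(b1-4)GlcNAc(b1-4)GlcNAc"
    return [
        # --- N-glycans (biantennary scaffolds on the trimannosyl core) ---
        t(
            "N_man5",
            "N",
            f"Man(a1-2)Man(a1-3)[Man(a1-6)]{n_core}",
            {"antennarity": 0},
        ),
        t(
            "N_bi_agalacto",
            "N",
            f"GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)]{n_core}",
            {"antennarity": 2},
        ),
        t(
            "N_bi_galacto",
            "N",
            f"Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]{n_core}",
            {"LacNAc": 2, "antennarity": 2},
        ),
        t(
            "N_bi_sia23",
            "N",
            "Neu5Ac(a2-3)Gal(b1-4)GlcNAc(b1-2)Man(a1-3)"
            f"[Neu5Ac(a2-3)Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]{n_core}",
            {"a2,3-sialylation": 2, "LacNAc": 2, "antennarity": 2},
            frozenset({"sial"}),
        ),
        t(
            "N_bi_sia26",
            "N",
            "Neu5Ac(a2-6)Gal(b1-4)GlcNAc(b1-2)Man(a1-3)"
            f"[Neu5Ac(a2-6)Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]{n_core}",
            {"a2,6-sialylation": 2, "LacNAc": 2, "antennarity": 2},
            frozenset({"sial"}),
        ),
        t(
            "N_bi_slex2",
            "N",
            "Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-2)Man(a1-3)"
            f"[Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-2)Man(a1-6)]{n_core}",
            {
                "(s)Lex/a": 2,
                "sLex": 2,
                "a2,3-sialylation": 2,
                "LacNAc": 2,
                "antennarity": 2,
            },
            frozenset({"slexa"}),
        ),
        t(
            "N_bi_slex1",
            "N",
            "Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-2)Man(a1-3)"
            f"[Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]{n_core}",
            {
                "(s)Lex/a": 1,
                "sLex": 1,
                "a2,3-sialylation": 1,
                "LacNAc": 2,
                "antennarity": 2,
            },
            frozenset({"slexa"}),
        ),
        t(
            "N_tri_lex",
            "N",
            "Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-2)Man(a1-3)"
            "[Gal(b1-4)GlcNAc(b1-2)[Gal(b1-4)GlcNAc(b1-6)]Man(a1-6)]"
            f"{n_core}",
            {"(s)Lex/a": 1, "Lex": 1, "LacNAc": 3, "antennarity": 3},
            frozenset({"slexa"}),
        ),
        # --- O-glycans ---
        t("O_tn", "O", "GalNAc", {}),
        t("O_t_antigen", "O", "Gal(b1-3)GalNAc", {"T antigen": 1}),
        t(
            "O_sialyl_t",
            "O",
            "Neu5Ac(a2-3)Gal(b1-3)GalNAc",
            {"a2,3-sialylation": 1},
            frozenset({"sial"}),
        ),
        t(
            "O_disialyl_t",
            "O",
            "Neu5Ac(a2-3)Gal(b1-3)[Neu5Ac(a2-6)]GalNAc",
            {"a2,3-sialylation": 1, "a2,6-sialylation": 1},
            frozenset({"sial"}),
        ),
        t(
            "O_core2_slex",
            "O",
            "Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-6)[Gal(b1-3)]GalNAc",
            {
                "(s)Lex/a": 1,
                "sLex": 1,
                "a2,3-sialylation": 1,
                "LacNAc": 1,
                "core 2": 1,
            },
            frozenset({"slexa"}),
        ),
        t(
            "O_core2_sulfo",
            "O",
            "Gal(b1-4)GlcNAc6S(b1-6)[Gal(b1-3)]GalNAc",
            {"LacNAc": 1, "core 2": 1, "sulfation": 1},
        ),
        t(
            "O_h_core1",
            "O",
            "Fuc(a1-2)Gal(b1-3)GalNAc",
            {"H antigen": 1},
            frozenset({"h"}),
        ),
        t(
            "O_disia28",
            "O",
            "Neu5Ac(a2-8)Neu5Ac(a2-3)Gal(b1-3)GalNAc",
            {"a2,8-sialylation": 1, "a2,3-sialylation": 1},
            frozenset({"sial"}),
        ),
        # --- GSL-glycans (on the lactosylceramide core Gal(b1-4)Glc) ---
        t("GSL_lactose", "GSL", "Gal(b1-4)Glc", {}),
        t(
            "GSL_gm3",
            "GSL",
            "Neu5Ac(a2-3)Gal(b1-4)Glc",
            {"a2,3-sialylation": 1, "gangliosides": 1},
            frozenset({"sial"}),
        ),
        t(
            "GSL_gd3",
            "GSL",
            "Neu5Ac(a2-8)Neu5Ac(a2-3)Gal(b1-4)Glc",
            {"a2,8-sialylation": 1, "a2,3-sialylation": 1, "gangliosides": 1},
            frozenset({"sial"}),
        ),
        t(
            "GSL_gm3_neu5gc",
            "GSL",
            "Neu5Gc(a2-3)Gal(b1-4)Glc",
            {"Neu5Gc": 1, "a2,3-sialylation": 1, "gangliosides": 1},
            frozenset({"sial"}),
        ),
        t(
            "GSL_nlc4_h",
            "GSL",
            "Fuc(a1-2)Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc",
            {"H antigen": 1, "LacNAc": 1},
            frozenset({"h"}),
        ),
        t(
            "GSL_nlc4_slex",
            "GSL",
            "Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-3)Gal(b1-4)Glc",
            {
                "(s)Lex/a": 1,
                "sLex": 1,
                "a2,3-sialylation": 1,
                "LacNAc": 1,
                "gangliosides": 1,
            },
            frozenset({"slexa"}),
        ),
        t(
            "GSL_gm1",
            "GSL",
            "Gal(b1-3)GalNAc(b1-4)[Neu5Ac(a2-3)]Gal(b1-4)Glc",
            {"a2,3-sialylation": 1, "gangliosides": 1},
            frozenset({"sial"}),
        ),
        t(
            "GSL_sia26_nlc4",
            "GSL",
            "Neu5Ac(a2-6)Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc",
            {"a2,6-sialylation": 1, "LacNAc": 1, "gangliosides": 1},
            frozenset({"sial"}),
        ),
    ]


@dataclass(frozen=True)
class Coupling:
    """A planted monotone association ``gene = effect · z(driver) + noise``."""

    gene: str
    driver: str  # trait name (GST couplings) or gene name (TF couplings)
    effect: float


DEFAULT_GST_COUPLINGS = (
    Coupling("FUT7", "(s)Lex/a", 1.0),
    Coupling("FUT4", "(s)Lex/a", 0.8),
    Coupling("FUT1", "H antigen", 1.0),
    Coupling("ST3GAL1", "a2,3-sialylation", 1.0),
    Coupling("ST3GAL2", "a2,3-sialylation", 0.8),
    Coupling("ST6GALNAC1", "a2,6-sialylation", 1.0),
    Coupling("ST6GALNAC6", "a2,6-sialylation", -1.0),
    Coupling("ST8SIA6", "a2,8-sialylation", 1.0),
)

DEFAULT_TF_COUPLINGS = (
    Coupling("SPI1", "FUT7", 1.0),
    Coupling("CEBPA", "FUT7", 0.8),
    Coupling("CEBPA", "FUT4", 0.8),
    Coupling("GATA1", "ST3GAL2", 1.0),
    Coupling("GATA1", "FUT7", -0.8),
    Coupling("TAL1", "ST6GALNAC1", 1.0),
    Coupling("RUNX1", "ST8SIA6", 1.0),
    Coupling("CBFA2T3", "ST8SIA6", 0.8),
)

#: Panel members without planted couplings are generated as pure noise.
DEFAULT_GST_PANEL = [
    "ST3GAL1",
    "ST3GAL2",
    "ST3GAL4",
    "ST6GAL1",
    "ST6GALNAC1",
    "ST6GALNAC4",
    "ST6GALNAC6",
    "ST8SIA1",
    "ST8SIA6",
    "FUT1",
    "FUT2",
    "FUT4",
    "FUT7",
    "FUT9",
    "B4GALT1",
]

DEFAULT_TF_PANEL = [
    "SPI1",
    "CEBPA",
    "GATA1",
    "GATA2",
    "GATA3",
    "RUNX1",
    "TAL1",
    "CBFA2T3",
    "MECOM",
    "MYB",
]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the cell-line setting the pipeline targets: 19 samples
    dominated by M5/M6 groups, ~20 glycans per class, moderate compositional
    noise, and clearly planted but noisy expression couplings.
    """

    seed: int
    n_samples: int = 19
    fab_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "M1": 2 / 19,
            "M2": 3 / 19,
            "M4": 3 / 19,
            "M5": 6 / 19,
            "M6": 5 / 19,
        }
    )
    n_glycans_per_class: dict[str, int] = field(
        default_factory=lambda: {"N": 20, "O": 20, "GSL": 20}
    )
    #: tag -> {group: multiplicative shift on target weights}
    group_shifts: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "slexa": {"M5": 3.0},
            "sial": {"M6": 2.5},
            "h": {"M4": 2.0},
        }
    )
    #: Dirichlet concentration (total mass); None = noise-free compositions.
    dirichlet_concentration: float | None = 300.0
    expression_noise_sd: float = 0.5
    expression_baseline: float = 8.0
    gst_couplings: tuple[Coupling, ...] = DEFAULT_GST_COUPLINGS
    tf_couplings: tuple[Coupling, ...] = DEFAULT_TF_COUPLINGS
    gst_panel: tuple[str, ...] = tuple(DEFAULT_GST_PANEL)
    tf_panel: tuple[str, ...] = tuple(DEFAULT_TF_PANEL)
    other_genes: tuple[str, ...] = ("ACTB", "GAPDH", "B2M")
    templates: tuple[GlycanTemplate, ...] | None = None  # None = default library

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        total = sum(self.fab_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"FAB proportions sum to {total}, expected 1")
        for c in list(self.gst_couplings) + list(self.tf_couplings):
            if not np.isfinite(c.effect):
                raise ValueError(f"non-finite effect size for {c.gene}")
        for cls, n in self.n_glycans_per_class.items():
            if n < 1:
                raise ValueError(f"need at least one glycan for class {cls!r}")
        for tpl in self.templates or default_templates():
            n_residues = len(parse_glycan(tpl.structure, tpl.glycan_class))
            worst = max(tpl.trait_counts.values(), default=0)
            if worst > n_residues:
                raise ValueError(
                    f"template {tpl.name!r} plants {worst} epitopes on "
                    f"{n_residues} residues; infeasible"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gst_couplings"] = [asdict(c) for c in self.gst_couplings]
        d["tf_couplings"] = [asdict(c) for c in self.tf_couplings]
        if self.templates is not None:
            d["templates"] = [asdict(t) | {"tags": sorted(t.tags)} for t in self.templates]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Everything planted: exact traits, coupling signs, group shifts."""

    trait_matrices: dict[str, pd.DataFrame]  # class -> samples × traits (exact)
    integrated_traits: pd.DataFrame
    glycan_counts: dict[str, pd.DataFrame]  # class -> glycans × traits
    gst_coupling_signs: dict[tuple[str, str], int]  # (gene, trait) -> ±1
    tf_coupling_signs: dict[tuple[str, str], int]  # (tf, gst) -> ±1
    group_shifts: dict[str, dict[str, float]]


@dataclass
class Cohort:
    panels: dict[str, GlycomicsPanel]
    expression: ExpressionMatrix
    fab_labels: pd.Series
    ground_truth: GroundTruth
    config: SynthConfig


def _fab_assignment(cfg: SynthConfig) -> pd.Series:
    """Deterministic largest-remainder apportionment of samples to groups."""
    groups = sorted(cfg.fab_proportions)
    raw = {g: cfg.fab_proportions[g] * cfg.n_samples for g in groups}
    counts = {g: int(np.floor(raw[g])) for g in groups}
    leftover = cfg.n_samples - sum(counts.values())
    by_frac = sorted(groups, key=lambda g: (-(raw[g] - counts[g]), g))
    for g in by_frac[:leftover]:
        counts[g] += 1
    labels = []
    for g in groups:
        labels.extend([g] * counts[g])
    samples = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    return pd.Series(labels, index=samples, name="fab")


def _trait_union(templates: list[GlycanTemplate], glycan_class: str) -> list[str]:
    traits: list[str] = []
    for tpl in templates:
        if tpl.glycan_class != glycan_class:
            continue
        for t in tpl.trait_counts:
            if t not in traits:
                traits.append(t)
    return sorted(traits)


def _shift_factor(cfg: SynthConfig, tags: frozenset[str], group: str) -> float:
    factor = 1.0
    for tag in sorted(tags):
        factor *= cfg.group_shifts.get(tag, {}).get(group, 1.0)
    return factor


def generate_cohort(
    cfg: SynthConfig,
    *,
    sample_prefix: str = "S",
    noise_seed: int | None = None,
) -> Cohort:
    """Generate one cohort (glycomics × 3 classes, expression, FAB labels).

    Fully deterministic given ``cfg.seed``.  The cohort *structure* (glycan
    base compositions) is drawn from ``cfg.seed`` while the sampling noise
    (Dirichlet compositions, expression noise) is drawn from ``noise_seed``
    (default: the same seed); noise replicates of one cohort share the seed
    but use different noise seeds.
    """
    rng_struct = np.random.default_rng([cfg.seed, 0])
    rng = np.random.default_rng([cfg.seed if noise_seed is None else noise_seed, 1])
    fab = _fab_assignment(cfg)
    if sample_prefix != "S":
        fab.index = [s.replace("S", sample_prefix, 1) for s in fab.index]
    samples = list(fab.index)
    templates = list(cfg.templates or default_templates())

    panels: dict[str, GlycomicsPanel] = {}
    truth_traits: dict[str, pd.DataFrame] = {}
    truth_counts: dict[str, pd.DataFrame] = {}
    for glycan_class in ("N", "O", "GSL"):
        class_templates = [t for t in templates if t.glycan_class == glycan_class]
        if not class_templates:
            raise ValueError(f"no templates for glycan class {glycan_class!r}")
        n_glycans = cfg.n_glycans_per_class.get(glycan_class, len(class_templates))
        chosen = [class_templates[i % len(class_templates)] for i in range(n_glycans)]
        glycan_ids = [
            f"{glycan_class}{i + 1:03d}_{tpl.name}" for i, tpl in enumerate(chosen)
        ]
        base_weights = rng_struct.gamma(shape=2.0, scale=1.0, size=n_glycans) + 0.2

        abundance = np.empty((n_glycans, len(samples)))
        for j, sample in enumerate(samples):
            group = fab.loc[sample]
            target = np.array(
                [
                    w * _shift_factor(cfg, tpl.tags, group)
                    for w, tpl in zip(base_weights, chosen)
                ]
            )
            target = target / target.sum()
            if cfg.dirichlet_concentration is None:
                props = target
            else:
                props = rng.dirichlet(target * cfg.dirichlet_concentration)
            abundance[:, j] = props * 100.0

        traits = _trait_union(templates, glycan_class)
        counts = pd.DataFrame(
            [[tpl.trait_counts.get(t, 0.0) for t in traits] for tpl in chosen],
            index=glycan_ids,
            columns=traits,
        )
        # Analytic ground truth by plain nested-loop accumulation.
        exact = np.zeros((len(samples), len(traits)))
        for si in range(len(samples)):
            for ti, trait in enumerate(traits):
                acc = 0.0
                for gi in range(n_glycans):
                    acc += abundance[gi, si] * counts.iat[gi, ti]
                exact[si, ti] = acc
        truth_traits[glycan_class] = pd.DataFrame(exact, index=samples, columns=traits)
        truth_counts[glycan_class] = counts

        records = [
            GlycanRecord(glycan_id=gid, structure_text=tpl.structure)
            for gid, tpl in zip(glycan_ids, chosen)
        ]
        panels[glycan_class] = GlycomicsPanel(
            glycan_class=glycan_class,
            glycans=records,
            abundances=pd.DataFrame(abundance, index=glycan_ids, columns=samples),
            fab_labels=fab,
        )

    integrated = integrate_traits(
        [
            TraitMatrix(truth_traits[c], glycan_class=c, provenance="ground-truth")
            for c in ("N", "O", "GSL")
        ]
    ).values

    # --- expression ---
    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1)
        if sd == 0:
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    n = len(samples)
    expr_rows: dict[str, np.ndarray] = {}
    gst_signal: dict[str, np.ndarray] = {}
    for gene in cfg.gst_panel:
        plant = [c for c in cfg.gst_couplings if c.gene == gene]
        signal = np.zeros(n)
        for c in plant:
            if c.driver not in integrated.columns:
                raise ValueError(f"coupling driver trait {c.driver!r} not generated")
            signal += c.effect * zscore(integrated[c.driver].to_numpy())
        gst_signal[gene] = signal
        expr_rows[gene] = (
            cfg.expression_baseline
            + signal
            + cfg.expression_noise_sd * rng.standard_normal(n)
        )
    for gene in cfg.tf_panel:
        plant = [c for c in cfg.tf_couplings if c.gene == gene]
        signal = np.zeros(n)
        for c in plant:
            if c.driver not in gst_signal:
                raise ValueError(f"TF coupling target {c.driver!r} is not a GST panel gene")
            signal += c.effect * zscore(gst_signal[c.driver])
        expr_rows[gene] = (
            cfg.expression_baseline
            + signal
            + cfg.expression_noise_sd * rng.standard_normal(n)
        )
    for gene in cfg.other_genes:
        expr_rows[gene] = cfg.expression_baseline + rng.standard_normal(n)

    values = pd.DataFrame(expr_rows, index=samples).T
    panels_cfg = [
        GenePanel("GST", list(cfg.gst_panel)),
        GenePanel("TF", list(cfg.tf_panel)),
    ]
    expression = ExpressionMatrix(
        values=values,
        panel_tags=attach_panels(values, panels_cfg),
        fab_labels=fab,
    )

    truth = GroundTruth(
        trait_matrices=truth_traits,
        integrated_traits=integrated,
        glycan_counts=truth_counts,
        gst_coupling_signs={
            (c.gene, c.driver): int(np.sign(c.effect)) for c in cfg.gst_couplings
        },
        tf_coupling_signs={
            (c.gene, c.driver): int(np.sign(c.effect)) for c in cfg.tf_couplings
        },
        group_shifts=cfg.group_shifts,
    )
    return Cohort(
        panels=panels,
        expression=expression,
        fab_labels=fab,
        ground_truth=truth,
        config=cfg,
    )


def generate_cohort_pair(
    cfg: SynthConfig,
    *,
    n_samples_second: int | None = None,
) -> tuple[Cohort, Cohort]:
    """Two cohorts ("cell-line-like", "primary-like") sharing all couplings.

    The second cohort uses an independent noise stream (seed offset) and
    optionally a different sample size, exercising the cross-cohort RV2
    bridge on matrices with known shared structure.
    """
    first = generate_cohort(cfg, sample_prefix="C")
    second_cfg = replace(cfg, n_samples=n_samples_second or cfg.n_samples)
    second = generate_cohort(
        second_cfg,
        sample_prefix="P",
        noise_seed=(cfg.seed + 104729) % (2**31),
    )
    return first, second


def write_fixture_set(cfg: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort as the documented TSV bundle plus ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cfg)
    paths: dict[str, Path] = {}
    for glycan_class, panel in cohort.panels.items():
        p = out / f"glycomics_{glycan_class}.tsv"
        write_glycomics_table(panel, p)
        paths[f"glycomics_{glycan_class}"] = p
    p = out / "expression.tsv"
    write_expression_matrix(cohort.expression, p)
    paths["expression"] = p
    p = out / "fab_labels.tsv"
    cohort.fab_labels.rename_axis("sample_id").to_frame().to_csv(p, sep="\t")
    paths["fab_labels"] = p
    p = out / "ground_truth.json"
    truth = cohort.ground_truth
    with open(p, "w") as fh:
        json.dump(
            {
                "trait_matrices": {
                    c: df.round(12).to_dict(orient="index")
                    for c, df in truth.trait_matrices.items()
                },
                "integrated_traits": truth.integrated_traits.round(12).to_dict(
                    orient="index"
                ),
                "gst_coupling_signs": {
                    f"{g}->{t}": s for (g, t), s in truth.gst_coupling_signs.items()
                },
                "tf_coupling_signs": {
                    f"{g}->{t}": s for (g, t), s in truth.tf_coupling_signs.items()
                },
                "group_shifts": truth.group_shifts,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    paths["ground_truth"] = p
    p = out / "manifest.json"
    write_manifest({"seed": cfg.seed, "config_hash": cfg.config_hash()}, p)
    paths["manifest"] = p
    return paths
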