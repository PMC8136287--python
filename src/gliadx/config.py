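"""Simulation configurations.

:func:`default_config` returns, for each brain cell type, the configuration
whose planted effects mirror the published censuses for the DMSXL (DM)
vs. WT comparison: numbers of differentially expressed genes, misspliced
events per category, differentiation-regulated features and their
concordance split, phosphosite counts, and per-nucleus foci statistics.

All counts and thresholds are plain dataclass fields, serializable to a
flat YAML mapping, so every stage threshold can be overridden from a
config file.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .tables import CELL_TYPES, EVENT_CATEGORIES


class ConfigError(ValueError):
    pass


@dataclass
class ExpressionConcordancePlan:
    """How disease DE genes relate to the WT differentiation program.

    Counts partition the planted DE genes into concordance classes; genes
    not covered by any class are disease-only (absent from the catalog).
    """

    failed_activation: int = 0   # catalog up, disease down
    failed_repression: int = 0   # catalog down, disease up
    accentuated_up: int = 0      # catalog up, disease up
    accentuated_down: int = 0    # catalog down, disease down

    @property
    def total(self) -> int:
        return (
            self.failed_activation
            + self.failed_repression
            + self.accentuated_up
            + self.accentuated_down
        )


@dataclass
class ExpressionSim:
    """Negative-binomial gene count simulation."""

    n_genes: int = 16000
    n_replicates: int = 4
    log_mu_mean: float = math.log(250.0)   # gene baseline: log-normal
    log_mu_sigma: float = 1.2
    dispersion: float = 0.005              # NB dispersion across replicate cultures
    size_factor_sigma: float = 0.15        # log-normal per-sample depth factor
    planted_min_mu: float = 500.0          # planted effects sit on expressed genes
    planted_max_mu: float = 5000.0
    n_de_up: int = 0
    n_de_down: int = 0
    de_log2fc: float = 2.0                 # 4-fold planted genotype effect
    n_diff_genes: int = 0                  # WT precursor -> differentiated program
    diff_log2fc: float = 2.0
    stages: tuple[str, ...] = ("differentiated",)
    comparison_stage: str = "differentiated"
    concordance: Optional[ExpressionConcordancePlan] = None

    @property
    def n_de(self) -> int:
        return self.n_de_up + self.n_de_down

    def validate(self) -> None:
        if self.n_de > self.n_genes:
            raise ConfigError("planted DE genes exceed total genes")
        if self.n_diff_genes > self.n_genes:
            raise ConfigError("planted differentiation genes exceed total genes")
        if self.concordance is not None:
            if self.concordance.total > self.n_de:
                raise ConfigError("concordance plan exceeds planted DE genes")
            up = self.concordance.failed_repression + self.concordance.accentuated_up
            if up > self.n_de_up:
                raise ConfigError("concordance plan needs more up-genes than planted")
        if self.n_diff_genes and len(self.stages) < 2:
            raise ConfigError("differentiation program requires >= 2 stages")
        if self.comparison_stage not in self.stages:
            raise ConfigError("comparison_stage must be among stages")


@dataclass
class TrajectoryPlan:
    """Three-stage splicing program (precursor -> intermediate -> differentiated).

    ``n_early_only`` events complete their PSI transition before the
    intermediate stage, ``n_late_only`` change only across the final
    maturation step (transient at the intermediate stage), ``n_both``
    change across both screened transitions.
    """

    n_early_only: int = 0
    n_late_only: int = 0
    n_both: int = 0

    @property
    def total(self) -> int:
        return self.n_early_only + self.n_late_only + self.n_both


@dataclass
class SplicingConcordancePlan:
    """Direction split of disease events that are differentiation-regulated."""

    n_immature: int = 0  # disease shift opposes the maturation shift
    n_mature: int = 0    # disease shift exaggerates the maturation shift

    @property
    def total(self) -> int:
        return self.n_immature + self.n_mature


@dataclass
class SplicingSim:
    """Binomial inclusion-count simulation over five event categories."""

    n_events: dict = field(
        default_factory=lambda: {
            "cassette": 6000,
            "multi_exon": 1500,
            "mutually_exclusive": 800,
            "acceptor_switch": 900,
            "donor_switch": 800,
        }
    )
    n_true: dict = field(default_factory=lambda: {c: 0 for c in EVENT_CATEGORIES})
    n_replicates: int = 4
    delta_psi: float = 30.0                # planted disease shift, PSI points
    diff_delta_psi: float = 30.0           # planted maturation shift, PSI points
    read_depth_mean: float = 100.0         # informative reads per event/sample
    read_depth_dispersion: float = 0.05
    n_shared: int = 0                      # events shared with the partner glia
    shared_prefix: str = "SHGL"            # common astro/OL event-id namespace
    # per-category index where this cell type's planted events start, so the
    # four cell types occupy disjoint blocks of one genome-wide event catalog
    plant_offsets: dict = field(default_factory=dict)
    stages: tuple[str, ...] = ("differentiated",)
    comparison_stage: str = "differentiated"
    n_diff_events: int = 0                 # two-stage differentiation catalog size
    trajectory: Optional[TrajectoryPlan] = None  # three-stage alternative
    concordance: Optional[SplicingConcordancePlan] = None

    @property
    def n_true_total(self) -> int:
        return sum(self.n_true.values())

    def validate(self) -> None:
        for cat, n in self.n_true.items():
            if cat not in EVENT_CATEGORIES:
                raise ConfigError(f"unknown event category {cat!r}")
            if self.plant_offsets.get(cat, 0) + n > self.n_events.get(cat, 0):
                raise ConfigError(f"planted {cat} events exceed total")
        if self.n_shared > self.n_true.get("cassette", 0):
            raise ConfigError("shared events exceed planted cassette events")
        if self.trajectory is not None and len(self.stages) != 3:
            raise ConfigError("trajectory plan requires three stages")
        if self.concordance is not None:
            ncat = self.trajectory.total if self.trajectory else self.n_diff_events
            if self.concordance.total > ncat:
                raise ConfigError("concordance plan exceeds differentiation events")
        if self.comparison_stage not in self.stages:
            raise ConfigError("comparison_stage must be among stages")


@dataclass
class PhosphoSim:
    """Label-free phosphosite intensity simulation with detection dropout."""

    n_sites: int = 3000
    n_replicates: int = 4
    n_up: int = 0
    n_down: int = 0
    exclusive_fraction: float = 0.3        # significant sites that are all-or-none
    log2fc: float = 1.0                    # quantitative planted effect (2-fold)
    residual_sd: float = 0.15              # per-sample log2 intensity noise
    baseline_mean: float = 22.0            # log2 LFQ intensity scale
    baseline_sd: float = 2.0
    missing_rate: float = 0.10             # stochastic dropout on null sites only
    n_significant_proteins: int = 0        # proteins carrying the planted sites
    n_overlap_missplicing: int = 0         # of which encoded by misspliced genes

    @property
    def n_significant(self) -> int:
        return self.n_up + self.n_down

    def validate(self) -> None:
        if self.n_significant > self.n_sites:
            raise ConfigError("planted phospho sites exceed total sites")
        if not 0 <= self.exclusive_fraction <= 1:
            raise ConfigError("exclusive_fraction must be in [0,1]")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0,1)")
        if self.n_significant_proteins:
            if not self.n_significant_proteins <= self.n_significant:
                raise ConfigError("more significant proteins than sites")
            if self.n_overlap_missplicing > self.n_significant_proteins:
                raise ConfigError("overlap exceeds significant proteins")


@dataclass
class FociSim:
    """Zero-inflated Poisson foci-per-nucleus model (DM nuclei; WT are zero)."""

    fraction_positive: float = 0.5  # P(count > 0) over all DM nuclei
    mean_count: float = 2.0         # mean foci over all DM nuclei
    n_cells: int = 500

    def validate(self) -> None:
        if not 0 < self.fraction_positive <= 1:
            raise ConfigError("fraction_positive must be in (0,1]")
        if self.mean_count <= 0:
            raise ConfigError("mean_count must be positive")
        # (1-e^-lam)/lam in (0,1) strictly decreasing; solvable iff ratio < 1
        # and the implied occupancy 1-pi = mean/lam does not exceed 1.
        if self.fraction_positive >= 1 and self.mean_count < 1:
            raise ConfigError("fraction_positive 1 requires mean >= ... infeasible")
        if self.fraction_positive / self.mean_count >= 1.0 and self.fraction_positive < 1:
            raise ConfigError(
                "infeasible foci parameters: need fraction_positive < mean_count "
                "for a zero-inflated Poisson"
            )


@dataclass
class SimulationConfig:
    """Everything needed to generate one cell type's synthetic inputs."""

    cell_type: str
    expression: ExpressionSim = field(default_factory=ExpressionSim)
    splicing: SplicingSim = field(default_factory=SplicingSim)
    phospho: Optional[PhosphoSim] = None
    foci: FociSim = field(default_factory=FociSim)
    seed: Optional[int] = None
    # stage-analysis thresholds (every filter has a config key)
    fc_threshold: float = 1.4
    dpsi_threshold: float = 10.0
    alpha: float = 0.05
    min_reads: int = 10

    def validate(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ConfigError(f"unknown cell_type {self.cell_type!r}")
        self.expression.validate()
        self.splicing.validate()
        if self.phospho is not None:
            self.phospho.validate()
        self.foci.validate()

    # -- flat YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        expr = dict(data.pop("expression", {}))
        conc = expr.pop("concordance", None)
        if conc is not None:
            conc = ExpressionConcordancePlan(**conc)
        expr = ExpressionSim(**{**expr, "concordance": conc})
        expr.stages = tuple(expr.stages)
        spl = dict(data.pop("splicing", {}))
        traj = spl.pop("trajectory", None)
        if traj is not None:
            traj = TrajectoryPlan(**traj)
        sconc = spl.pop("concordance", None)
        if sconc is not None:
            sconc = SplicingConcordancePlan(**sconc)
        spl = SplicingSim(**{**spl, "trajectory": traj, "concordance": sconc})
        spl.stages = tuple(spl.stages)
        pho = data.pop("phospho", None)
        if pho is not None:
            pho = PhosphoSim(**pho)
        foci = FociSim(**data.pop("foci", {}))
        cfg = cls(expression=expr, splicing=spl, phospho=pho, foci=foci, **data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# -- published-census defaults ------------------------------------------------

#: total detected transcripts per cell type
N_GENES = {"neuron": 17089, "OPC": 15845, "OL": 16070, "astrocyte": 16878}

#: significant misspliced events per category (cassette counts are printed;
#: non-cassette splits are graphical-only and chosen to sum to the printed
#: totals: OL 101 with 84 exon-block events, astrocyte 264, neuron 18, OPC 16)
SPLICE_CENSUS = {
    "astrocyte": {
        "cassette": 184,
        "multi_exon": 40,
        "mutually_exclusive": 20,
        "acceptor_switch": 10,
        "donor_switch": 10,
    },
    "OL": {
        "cassette": 65,
        "multi_exon": 12,
        "mutually_exclusive": 7,
        "acceptor_switch": 9,
        "donor_switch": 8,
    },
    "neuron": {
        "cassette": 11,
        "multi_exon": 3,
        "mutually_exclusive": 2,
        "acceptor_switch": 1,
        "donor_switch": 1,
    },
    "OPC": {
        "cassette": 8,
        "multi_exon": 3,
        "mutually_exclusive": 2,
        "acceptor_switch": 2,
        "donor_switch": 1,
    },
}

#: foci-per-nucleus parameters (fraction of positive nuclei, mean over all nuclei)
FOCI_PARAMS = {
    "astrocyte": (0.95, 6.0),
    "neuron": (0.70, 2.4),
    "OPC": (0.20, 1.4),
    "OL": (0.50, 2.5),
}

#: DM vs WT DE gene counts; only the OL number (85) is printed in the text
DE_CENSUS = {
    "OL": (2, 83),       # 2 up / 83 down
    "neuron": (3, 3),
    "OPC": (1, 2),
    "astrocyte": (5, 7),
}


def default_config(cell_type: str) -> SimulationConfig:
    """Configuration planting the published per-cell-type censuses.

    OL: 85 DE genes (2 up / 83 down) of which 80 are differentiation-
    regulated with 71 failed activations; 101 misspliced events (65
    cassette), 45 of the 84 exon-block events differentiation-regulated
    (37 immature / 8 mature shifts); 48 events shared with astrocytes.

    Astrocyte: 264 misspliced events (184 cassette); a 244-event
    differentiation splicing program assembled from 202 early- and 95
    late-transition changes sharing 53; 46 disease events overlap it
    (31 immature / 15 mature); 345 perturbed phosphosites (279 up / 66
    down) on 288 proteins, 27 overlapping misspliced genes.
    """
    if cell_type not in N_GENES:
        raise ConfigError(f"no default configuration for cell_type {cell_type!r}")
    up, down = DE_CENSUS[cell_type]
    expr = ExpressionSim(n_genes=N_GENES[cell_type], n_de_up=up, n_de_down=down)
    # the four cell types plant their disease events in disjoint index blocks
    # of one genome-wide event namespace (shared events are renamed anyway)
    order = ("neuron", "OPC", "OL", "astrocyte")
    offsets = {
        cat: sum(SPLICE_CENSUS[ct][cat] for ct in order[: order.index(cell_type)])
        for cat in SPLICE_CENSUS[cell_type]
    }
    spl = SplicingSim(n_true=dict(SPLICE_CENSUS[cell_type]), plant_offsets=offsets)
    phospho = None

    if cell_type == "OL":
        expr.stages = ("precursor", "differentiated")
        expr.n_diff_genes = 8140
        expr.concordance = ExpressionConcordancePlan(
            failed_activation=71,
            failed_repression=1,
            accentuated_up=1,
            accentuated_down=7,
        )
        spl.stages = ("precursor", "differentiated")
        spl.n_diff_events = 250
        spl.concordance = SplicingConcordancePlan(n_immature=37, n_mature=8)
        spl.n_shared = 48
    elif cell_type == "astrocyte":
        spl.stages = ("precursor", "intermediate", "differentiated")
        spl.trajectory = TrajectoryPlan(n_early_only=149, n_late_only=42, n_both=53)
        spl.concordance = SplicingConcordancePlan(n_immature=31, n_mature=15)
        spl.n_shared = 48
        phospho = PhosphoSim(
            n_up=279,
            n_down=66,
            n_significant_proteins=288,
            n_overlap_missplicing=27,
        )

    frac, mean = FOCI_PARAMS[cell_type]
    cfg = SimulationConfig(
        cell_type=cell_type,
        expression=expr,
        splicing=spl,
        phospho=phospho,
        foci=FociSim(fraction_positive=frac, mean_count=mean),
    )
    cfg.validate()
    return cfg


def null_config(cell_type: str = "OL", n_genes: int = 2000, n_events: int = 800,
                n_sites: int = 600) -> SimulationConfig:
    """A reduced-size configuration with no planted effects (global null)."""
    per_cat = {
        "cassette": int(n_events * 0.6),
        "multi_exon": int(n_events * 0.15),
        "mutually_exclusive": int(n_events * 0.08),
        "acceptor_switch": int(n_events * 0.09),
        "donor_switch": int(n_events * 0.08),
    }
    cfg = SimulationConfig(
        cell_type=cell_type,
        expression=ExpressionSim(n_genes=n_genes),
        splicing=SplicingSim(n_events=per_cat),
        phospho=PhosphoSim(n_sites=n_sites),
        foci=FociSim(fraction_positive=0.5, mean_count=2.0),
    )
    cfg.validate()
    return cfg
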