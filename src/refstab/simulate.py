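"""Synthetic Cq data with known ground truth.

The generator emulates a salt-stress RT-qPCR time course: candidate
reference genes whose Cq drifts with the treatment by a gene-specific
amplitude and response shape, genes of interest (GOIs) with known log2
fold-change trajectories, and two Gaussian noise layers on the Cq scale —
a biological deviate shared by all genes of a biological sample
(sample-loading variation, SD ``sigma_b``) and an independent technical
deviate per well (SD ``sigma_t``).

The well Cq is

    Cq[g,t,c,r,k] = mu_g + beta_g * f_g(c) + b[t,c,r] + eps[g,t,c,r,k]

for reference genes, where ``f_g`` is the gene's response shape
normalized to peak-to-peak 1 (so ``beta_g`` *is* the gene's true cycle
variation), and

    Cq[g,t,c,r,k] = mu_g - FC_g(c) / log2(E_g) + b[t,c,r] + eps[...]

for GOIs, where ``FC_g(c)`` is the true log2 fold change at condition c
relative to the first (control) condition.  Genes sharing a co-regulation
group id share the shape of the group's first member.

:func:`salt_stress_dataset` is a convenience preset mirroring a
three-tissue, six-time-point salt-stress design with 10 candidate
reference genes and 9 GOIs: triplicate biological and technical
replicates, gene mean Cq spread over roughly 19.6-32.4 cycles and
reference-gene amplitudes spanning 0.5-3.3 cycles.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import CqDataset, EfficiencyTable, PreconditionError

SHAPES = ("flat", "ramp_up", "ramp_down", "pulse_early", "pulse_late")


def shape_values(shape: str, n_conditions: int) -> np.ndarray:
    """Response shape over condition indices, normalized to [0, 1]."""
    if shape not in SHAPES:
        raise PreconditionError(f"unknown response shape {shape!r}")
    c = np.linspace(0.0, 1.0, n_conditions)
    if shape == "flat":
        return np.zeros(n_conditions)
    if shape == "ramp_up":
        return c
    if shape == "ramp_down":
        return 1.0 - c
    peak = 1.0 / 3.0 if shape == "pulse_early" else 2.0 / 3.0
    return np.where(c <= peak, c / peak, (1.0 - c) / (1.0 - peak))


@dataclasses.dataclass(frozen=True)
class GeneSpec:
    """One candidate reference gene.

    ``amplitude`` is the peak-to-peak condition response in cycles;
    ``shape`` describes how it unfolds over the condition axis.
    """

    name: str
    mean_cq: float
    efficiency: float = 2.0
    amplitude: float = 0.0
    shape: str = "flat"
    group: str | None = None


@dataclasses.dataclass(frozen=True)
class GoiSpec:
    """One gene of interest with its true log2 fold-change trajectory
    (one value per condition; the first, control, entry must be 0)."""

    name: str
    mean_cq: float
    efficiency: float = 2.0
    log2_trajectory: tuple = ()


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    genes: tuple
    gois: tuple = ()
    tissues: tuple = ("leaf",)
    conditions: tuple = ("0", "1")
    n_bio: int = 3
    n_tech: int = 3
    sigma_b: float = 0.2
    sigma_t: float = 0.1
    seed: int = 0

    def validate(self) -> list[str]:
        errs = []
        if len(self.conditions) < 2:
            errs.append("need at least 2 conditions")
        if self.n_bio < 1 or self.n_tech < 1:
            errs.append("replicate counts must be >= 1")
        if self.sigma_b < 0 or self.sigma_t < 0:
            errs.append("noise SDs must be >= 0")
        if not self.tissues:
            errs.append("need at least one tissue")
        names = [s.name for s in self.genes] + [s.name for s in self.gois]
        if len(set(names)) != len(names):
            errs.append("duplicate gene names")
        if len(self.genes) < 2:
            errs.append("need at least 2 reference genes")
        for s in self.genes:
            if not 0 < s.mean_cq < 45:
                errs.append(f"{s.name}: mean Cq must be in (0, 45)")
            if s.efficiency <= 1:
                errs.append(f"{s.name}: efficiency must exceed 1")
            if not np.isfinite(s.amplitude) or s.amplitude < 0:
                errs.append(f"{s.name}: amplitude must be >= 0")
            if s.shape not in SHAPES:
                errs.append(f"{s.name}: unknown shape {s.shape!r}")
        for s in self.gois:
            if s.efficiency <= 1:
                errs.append(f"{s.name}: efficiency must exceed 1")
            if len(s.log2_trajectory) != len(self.conditions):
                errs.append(
                    f"{s.name}: trajectory length {len(s.log2_trajectory)} != "
                    f"{len(self.conditions)} conditions"
                )
            elif s.log2_trajectory[0] != 0:
                errs.append(f"{s.name}: trajectory must start at 0 (control)")
        return errs


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: per-gene true cycle variation and
    per-GOI true log2 fold-change trajectories."""

    gene_table: pd.DataFrame  # gene, role, mean_cq, efficiency, amplitude, shape
    goi_trajectories: pd.DataFrame  # index condition, one column per GOI
    config: SimulationConfig

    @property
    def reference_genes(self) -> list[str]:
        tab = self.gene_table
        return list(tab.loc[tab["role"] == "reference", "gene"])

    @property
    def goi_genes(self) -> list[str]:
        tab = self.gene_table
        return list(tab.loc[tab["role"] == "goi", "gene"])

    def most_responsive(self, n: int = 2) -> list[str]:
        """The n reference genes with the largest true cycle variation."""
        tab = self.gene_table[self.gene_table["role"] == "reference"]
        return list(tab.sort_values(["amplitude", "gene"], ascending=[False, True])["gene"][:n])

    def least_responsive(self, n: int = 3) -> list[str]:
        tab = self.gene_table[self.gene_table["role"] == "reference"]
        return list(tab.sort_values(["amplitude", "gene"])["gene"][:n])


def efficiencies(config: SimulationConfig) -> EfficiencyTable:
    vals = {s.name: s.efficiency for s in list(config.genes) + list(config.gois)}
    return EfficiencyTable(vals)


def simulate_cq(config: SimulationConfig) -> tuple[CqDataset, GroundTruth]:
    """Draw one dataset; deterministic given ``config.seed``."""
    errs = config.validate()
    if errs:
        raise PreconditionError("invalid simulation config: " + "; ".join(errs))
    rng = np.random.default_rng(config.seed)
    tissues = list(config.tissues)
    conditions = list(config.conditions)
    t, c, r, k = len(tissues), len(conditions), config.n_bio, config.n_tech

    # co-regulated genes share the first group member's shape
    group_shape: dict[str, str] = {}
    for spec in config.genes:
        if spec.group is not None and spec.group not in group_shape:
            group_shape[spec.group] = spec.shape

    specs = list(config.genes) + list(config.gois)
    n_genes = len(specs)
    base = np.empty((n_genes, c))
    for gi, spec in enumerate(specs):
        if isinstance(spec, GeneSpec):
            shape = group_shape.get(spec.group, spec.shape)
            base[gi] = spec.mean_cq + spec.amplitude * shape_values(shape, c)
        else:
            fc = np.asarray(spec.log2_trajectory, dtype=float)
            base[gi] = spec.mean_cq - fc / np.log2(spec.efficiency)

    b = rng.normal(0.0, config.sigma_b, size=(t, c, r))
    eps = rng.normal(0.0, config.sigma_t, size=(n_genes, t, c, r, k))
    cq = base[:, None, :, None, None] + b[None, :, :, :, None] + eps

    gene_names = np.array([s.name for s in specs])
    idx = pd.MultiIndex.from_product(
        [gene_names, tissues, conditions, range(1, r + 1), range(1, k + 1)],
        names=["gene", "tissue", "condition", "bio_rep", "tech_rep"],
    )
    df = idx.to_frame(index=False)
    df["cq"] = cq.ravel()
    df["sample"] = (
        df["tissue"]
        + ":"
        + df["condition"]
        + ":b"
        + df["bio_rep"].astype(str)
        + ":t"
        + df["tech_rep"].astype(str)
    )
    ds = CqDataset(df[["gene", "sample", "tissue", "condition", "bio_rep", "tech_rep", "cq"]])

    gene_rows = []
    for spec in config.genes:
        gene_rows.append(
            {
                "gene": spec.name,
                "role": "reference",
                "mean_cq": spec.mean_cq,
                "efficiency": spec.efficiency,
                "amplitude": spec.amplitude,
                "shape": group_shape.get(spec.group, spec.shape),
            }
        )
    for spec in config.gois:
        traj = np.asarray(spec.log2_trajectory, dtype=float)
        cycle_var = float(np.ptp(traj / np.log2(spec.efficiency)))
        gene_rows.append(
            {
                "gene": spec.name,
                "role": "goi",
                "mean_cq": spec.mean_cq,
                "efficiency": spec.efficiency,
                "amplitude": cycle_var,
                "shape": "trajectory",
            }
        )
    goi_traj = pd.DataFrame(
        {s.name: list(s.log2_trajectory) for s in config.gois},
        index=pd.Index(conditions, name="condition"),
    )
    truth = GroundTruth(pd.DataFrame(gene_rows), goi_traj, config)
    return ds, truth


# ---------------------------------------------------------------------------
# Preset: three-tissue salt-stress time course
# ---------------------------------------------------------------------------

PRESET_TISSUES = ("leaf", "stem", "root")
PRESET_CONDITIONS = ("0", "1", "3", "6", "9", "12")  # hours of salt exposure

#: Ten candidate reference genes: mean Cq levels spread over the observed
#: expression range, standard-curve efficiencies, and condition-response
#: amplitudes spanning the 0.5-3.3 cycle spectrum with varied shapes.
PRESET_REFERENCE_GENES = (
    GeneSpec("60S", 23.5, 1.972, 0.9, "ramp_down"),
    GeneSpec("Actin", 24.8, 2.027, 2.6, "pulse_early"),
    GeneSpec("EF1a", 22.4, 1.896, 1.4, "ramp_up"),
    GeneSpec("eIF-5A", 23.0, 1.965, 0.7, "pulse_late"),
    GeneSpec("GAPDH", 24.2, 1.904, 1.1, "ramp_up"),
    GeneSpec("GIIa", 25.6, 2.009, 1.8, "ramp_down"),
    GeneSpec("HIS", 25.0, 1.968, 0.5, "pulse_early"),
    GeneSpec("RP", 22.8, 1.935, 0.6, "ramp_down"),
    GeneSpec("TUB", 29.6, 1.914, 3.3, "ramp_up"),
    GeneSpec("UBQ", 19.7, 2.097, 0.55, "ramp_up"),
)


def _traj(shape: str, peak_log2fc: float, n: int = len(PRESET_CONDITIONS)) -> tuple:
    return tuple(float(x) for x in peak_log2fc * shape_values(shape, n))


#: Nine salt-responsive genes of interest with induced trajectories.
PRESET_GOIS = (
    GoiSpec("PeCOBL4", 26.0, 1.887, _traj("ramp_up", 3.0)),
    GoiSpec("PeFLA12-1", 27.0, 1.944, _traj("pulse_early", 4.0)),
    GoiSpec("PeFLA12-2", 27.5, 2.031, _traj("pulse_late", 3.5)),
    GoiSpec("PeFLA12-3", 28.0, 2.074, _traj("ramp_up", 2.5)),
    GoiSpec("PeFLA12-4", 28.5, 2.049, _traj("pulse_early", 3.0)),
    GoiSpec("PeHKT1", 30.0, 2.054, _traj("ramp_up", 2.0)),
    GoiSpec("PeKUP3", 31.0, 1.978, _traj("pulse_late", 1.5)),
    GoiSpec("PeNhaD1", 31.5, 1.954, _traj("pulse_early", 2.0)),
    GoiSpec("PeNHX2", 32.3, 2.062, _traj("ramp_up", 5.0)),
)


def preset_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(
        genes=PRESET_REFERENCE_GENES,
        gois=PRESET_GOIS,
        tissues=PRESET_TISSUES,
        conditions=PRESET_CONDITIONS,
        n_bio=3,
        n_tech=3,
        sigma_b=0.2,
        sigma_t=0.1,
        seed=seed,
    )


def salt_stress_dataset(seed: int = 0):
    """Preset time-course dataset: ``(CqDataset, GroundTruth,
    EfficiencyTable)``.  Time point "0" is a complete control usable as
    the calibrator for every downstream operation."""
    config = preset_config(seed)
    ds, truth = simulate_cq(config)
    return ds, truth, efficiencies(config)


# ---------------------------------------------------------------------------
# Config (de)serialization
# ---------------------------------------------------------------------------

def config_to_yaml(config: SimulationConfig, path) -> None:
    doc = {
        "tissues": list(config.tissues),
        "conditions": list(config.conditions),
        "n_bio": config.n_bio,
        "n_tech": config.n_tech,
        "sigma_b": config.sigma_b,
        "sigma_t": config.sigma_t,
        "seed": config.seed,
        "genes": [
            {
                "name": s.name,
                "mean_cq": s.mean_cq,
                "efficiency": s.efficiency,
                "amplitude": s.amplitude,
                "shape": s.shape,
                **({"group": s.group} if s.group else {}),
            }
            for s in config.genes
        ],
        "gois": [
            {
                "name": s.name,
                "mean_cq": s.mean_cq,
                "efficiency": s.efficiency,
                "log2_trajectory": list(s.log2_trajectory),
            }
            for s in config.gois
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    genes = tuple(
        GeneSpec(
            name=str(g["name"]),
            mean_cq=float(g["mean_cq"]),
            efficiency=float(g.get("efficiency", 2.0)),
            amplitude=float(g.get("amplitude", 0.0)),
            shape=str(g.get("shape", "flat")),
            group=g.get("group"),
        )
        for g in doc.get("genes", [])
    )
    gois = tuple(
        GoiSpec(
            name=str(g["name"]),
            mean_cq=float(g["mean_cq"]),
            efficiency=float(g.get("efficiency", 2.0)),
            log2_trajectory=tuple(float(x) for x in g.get("log2_trajectory", [])),
        )
        for g in doc.get("gois", [])
    )
    return SimulationConfig(
        genes=genes,
        gois=gois,
        tissues=tuple(str(t) for t in doc.get("tissues", ["leaf"])),
        conditions=tuple(str(c) for c in doc.get("conditions", ["0", "1"])),
        n_bio=int(doc.get("n_bio", 3)),
        n_tech=int(doc.get("n_tech", 3)),
        sigma_b=float(doc.get("sigma_b", 0.2)),
        sigma_t=float(doc.get("sigma_t", 0.1)),
        seed=int(doc.get("seed", 0)),
    )
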