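"""Synthetic multi-image cohorts with known proximity effects.

The generator emulates a segmented multiplexed-imaging cohort: several
patients, a few images each, cells scattered uniformly over a square
field, types drawn from fixed proportions, and marker intensities built
from type-specific baselines plus Gaussian noise. Three mechanisms can be
switched on independently so every pipeline stage has an isolating
fixture:

* **planted proximity effects** — for a chosen (A, B, marker) triple the
  marker in A cells gains ``beta_true`` times the capped nearest-distance
  to B (or the abundance count), exactly the quantity the regression
  stage estimates, so truth and estimator share a scale;
* **lateral spillover** — every cell receives a fraction of each
  neighbour's (pre-spillover) expression decayed exponentially with
  distance, mimicking segmentation-boundary contamination;
* **linked survival** — each patient carries a latent risk score; planted
  effect sizes can be coupled to it, and survival times are exponential
  with hazard scaled by ``exp(log_hazard * risk)`` under independent
  uniform censoring calibrated to a target censoring fraction.

Negative intensities after noise are clipped at zero, matching the
non-negative semantics of quantified images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .io_data import CellDataset, ClinicalTable, MarkerClassification
from .spatial_metrics import abundance, nearest_distance


@dataclass
class PlantedCCM:
    """A true proximity effect: marker in type A responds to proximity to B."""

    cell_type_A: str
    cell_type_B: str
    marker: str
    beta_true: float
    effect_form: str = "linear_in_distance"  # or "linear_in_abundance"


@dataclass
class SpilloverConfig:
    decay_length: float = 12.0  # microns; e-folding scale, roughly one cell body
    leak_fraction: float = 0.8  # fraction of a neighbour's signal received at d=0
    conserve_mass: bool = False  # subtract leaked signal from the donor


@dataclass
class SurvivalConfig:
    baseline_scale: float = 365.0  # mean survival (days) at risk 0
    log_hazard: float = 1.0  # log-hazard per unit of patient risk
    censoring_fraction: float = 0.3
    risk_coupling: float = 0.0  # planted-slope shift per unit patient risk


@dataclass
class SyntheticConfig:
    n_patients: int = 10
    images_per_patient: int = 3
    cells_per_image: int = 800
    image_side: float = 1500.0  # microns
    type_proportions: dict[str, float] = field(default_factory=lambda: {
        "tumour": 0.40, "macrophage": 0.25, "tcell": 0.20, "stroma": 0.15,
    })
    # type x marker baseline means; keys are cell types
    baseline_expression: dict[str, dict[str, float]] | None = None
    noise_sd: float = 1.5
    planted_ccms: list[PlantedCCM] = field(default_factory=list)
    spillover: SpilloverConfig | None = None
    survival: SurvivalConfig | None = None
    radius: float = 200.0
    cap: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.type_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"type proportions sum to {total}, not 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.spillover is not None and not (0 <= self.spillover.leak_fraction < 1):
            raise ValueError("leak_fraction must lie in [0, 1)")
        if self.baseline_expression is None:
            self.baseline_expression = default_baselines(
                list(self.type_proportions))
        n_types = len(self.type_proportions)
        if self.cells_per_image < 2 * n_types:
            raise ValueError(
                f"{self.cells_per_image} cells per image cannot represent "
                f"{n_types} cell types")


#: marker panel of the default cohort: three defining markers per type (so
#: contamination moves several markers coherently, as in real panels) plus
#: shared state markers expressed everywhere at type-dependent levels
TYPE_MARKERS = {
    "panCK": "tumour", "CK7": "tumour", "Ecad": "tumour",
    "CD68": "macrophage", "CD11b": "macrophage", "CD14": "macrophage",
    "CD3": "tcell", "CD4": "tcell", "CD8": "tcell",
    "aSMA": "stroma", "vimentin": "stroma", "CD31": "stroma",
}
STATE_MARKERS = ["CD163", "Ki67", "PD1", "PDL1", "GranzymeB", "HLADR"]


def default_baselines(cell_types: list[str]) -> dict[str, dict[str, float]]:
    """Baseline panel: high own-type markers, low background elsewhere."""
    markers = {m: t for m, t in TYPE_MARKERS.items() if t in cell_types}
    base: dict[str, dict[str, float]] = {}
    for t in cell_types:
        row = {m: (5.0 if owner == t else 1.0) for m, owner in markers.items()}
        for k, m in enumerate(STATE_MARKERS):
            # state markers are expressed everywhere at type-dependent levels
            row[m] = 3.5 + 1.5 * ((hash_free_index(t) + k) % 3)
        base[t] = row
    return base


def hash_free_index(name: str) -> int:
    """Stable small index for a type name (no PYTHONHASHSEED dependence)."""
    return sum(ord(c) for c in name) % 5


def default_marker_classification(
    config: SyntheticConfig,
) -> MarkerClassification:
    markers = next(iter(config.baseline_expression.values())).keys()
    roles, owners = {}, {}
    for m in markers:
        if m in TYPE_MARKERS:
            roles[m] = "cell_type_specific"
            owners[m] = frozenset({TYPE_MARKERS[m]})
        else:
            roles[m] = "cell_state"
            owners[m] = frozenset()
    return MarkerClassification(roles, owners)


@dataclass
class GroundTruth:
    planted_ccms: list[PlantedCCM]
    pre_spillover_expression: pd.DataFrame
    patient_risk: pd.Series  # latent standard-normal risk per patient
    config: SyntheticConfig


def generate_cohort(config: SyntheticConfig) -> tuple[CellDataset, GroundTruth]:
    """Draw a full cohort (positions, types, expression) plus its truth.

    Cell positions are uniform over the image square, types multinomial,
    expression is baseline + N(0, noise_sd) + planted effects evaluated on
    the same capped metric the estimation stage uses. Spillover, when
    configured, is applied afterwards on top of the clean signal. Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    types = list(config.type_proportions)
    probs = np.array([config.type_proportions[t] for t in types])
    markers = list(next(iter(config.baseline_expression.values())).keys())
    base = pd.DataFrame(config.baseline_expression).T.loc[types, markers]

    patient_ids = [f"P{p:03d}" for p in range(config.n_patients)]
    patient_risk = pd.Series(
        rng.standard_normal(config.n_patients), index=patient_ids, name="risk")

    cells_frames, expr_blocks = [], []
    for p_idx, pid in enumerate(patient_ids):
        risk = patient_risk[pid]
        for k in range(config.images_per_patient):
            image_id = f"{pid}_img{k}"
            n = config.cells_per_image
            xy = rng.uniform(0, config.image_side, size=(n, 2))
            t_idx = rng.choice(len(types), size=n, p=probs)
            cell_types = np.array(types, dtype=object)[t_idx]
            cells = pd.DataFrame({
                "cell_id": [f"{image_id}_c{i}" for i in range(n)],
                "image_id": image_id,
                "patient_id": pid,
                "x": xy[:, 0],
                "y": xy[:, 1],
                "cell_type": cell_types,
            })
            expr = base.loc[cell_types].to_numpy(copy=True)
            expr += rng.normal(0.0, config.noise_sd, size=expr.shape)
            for planted in config.planted_ccms:
                beta = planted.beta_true
                if config.survival is not None:
                    beta = beta + config.survival.risk_coupling * risk
                a_mask = cell_types == planted.cell_type_A
                if not a_mask.any():
                    continue
                if planted.effect_form == "linear_in_distance":
                    metric, ok = nearest_distance(
                        cells, planted.cell_type_B, config.radius, config.cap)
                    metric = np.where(ok, metric, 0.0)
                elif planted.effect_form == "linear_in_abundance":
                    metric = abundance(
                        cells, planted.cell_type_B, config.radius).astype(float)
                else:
                    raise ValueError(
                        f"unknown effect_form {planted.effect_form!r}")
                j = markers.index(planted.marker)
                expr[a_mask, j] += beta * metric[a_mask]
            cells_frames.append(cells)
            expr_blocks.append(expr)

    cells_all = pd.concat(cells_frames, ignore_index=True)
    expression = pd.DataFrame(
        np.clip(np.concatenate(expr_blocks, axis=0), 0.0, None),
        index=pd.Index(cells_all["cell_id"], name="cell_id"),
        columns=markers,
    )
    dataset = CellDataset(cells_all, expression)
    truth = GroundTruth(
        planted_ccms=list(config.planted_ccms),
        pre_spillover_expression=expression.copy(),
        patient_risk=patient_risk,
        config=config,
    )
    if config.spillover is not None and config.spillover.leak_fraction > 0:
        dataset = inject_spillover(
            dataset,
            decay_length=config.spillover.decay_length,
            leak_fraction=config.spillover.leak_fraction,
            conserve_mass=config.spillover.conserve_mass,
        )
    return dataset, truth


def inject_spillover(
    dataset: CellDataset,
    decay_length: float,
    leak_fraction: float,
    conserve_mass: bool = False,
) -> CellDataset:
    """Contaminate each cell with exponentially decayed neighbour signal.

    Cell i gains sum_j leak * exp(-d_ij / decay) * E_j over neighbouring
    cells j of the same image, using the donors' original expression.
    Pairs beyond 8 decay lengths contribute < 4e-4 of the leak and are
    skipped. With ``conserve_mass`` the leaked amount is removed from the
    donor.
    """
    if not (0 <= leak_fraction < 1):
        raise ValueError("leak_fraction must lie in [0, 1)")
    if leak_fraction == 0:
        return dataset
    expr = dataset.expression.to_numpy(copy=True)
    donors = dataset.expression.to_numpy()
    row_pos = pd.Series(np.arange(dataset.n_cells), index=dataset.cells.index)
    cutoff = 8.0 * decay_length
    for image_id in dataset.image_ids:
        cells_img, _ = dataset.image_view(image_id)
        rows = row_pos[cells_img.index].to_numpy()
        xy = cells_img[["x", "y"]].to_numpy(dtype=float)
        tree = cKDTree(xy)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if not len(pairs):
            continue
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        w = leak_fraction * np.exp(-d / decay_length)
        gi, gj = rows[pairs[:, 0]], rows[pairs[:, 1]]
        np.add.at(expr, gi, w[:, None] * donors[gj])
        np.add.at(expr, gj, w[:, None] * donors[gi])
        if conserve_mass:
            np.add.at(expr, gj, -w[:, None] * donors[gj])
            np.add.at(expr, gi, -w[:, None] * donors[gi])
    expr = np.clip(expr, 0.0, None)
    return CellDataset(
        dataset.cells.copy(),
        pd.DataFrame(expr, index=dataset.expression.index,
                     columns=dataset.expression.columns),
    )


def _uniform_censor_bound(rate: float, censor_fraction: float) -> float:
    """Upper bound u of U(0, u) censoring s.t. P(T > C) = censor_fraction
    for T ~ Exp(rate)."""

    def frac(u):
        return (1.0 - np.exp(-rate * u)) / (rate * u) - censor_fraction

    # frac is decreasing in u from 1 (u->0) to 0 (u->inf)
    lo, hi = 1e-9, 1.0
    while frac(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            break
    return brentq(frac, lo, hi)


def generate_survival(
    ground_truth: GroundTruth, config: SyntheticConfig | None = None
) -> ClinicalTable:
    """Exponential survival times driven by the patients' latent risk.

    The hazard for patient i is ``exp(log_hazard * risk_i) /
    baseline_scale``; censoring is independent uniform with its upper
    bound solved per patient so the expected censoring fraction matches
    the configuration.
    """
    config = config or ground_truth.config
    surv = config.survival or SurvivalConfig()
    rng = np.random.default_rng((config.seed * 7919 + 13) % (2**31 - 1))
    risk = ground_truth.patient_risk
    rates = np.exp(surv.log_hazard * risk.to_numpy()) / surv.baseline_scale
    times = rng.exponential(1.0 / rates)
    events = np.ones(len(risk), dtype=int)
    if surv.censoring_fraction > 0:
        for i, rate in enumerate(rates):
            u = _uniform_censor_bound(rate, surv.censoring_fraction)
            c = rng.uniform(0.0, u)
            if c < times[i]:
                times[i], events[i] = c, 0
    times = np.maximum(times, 1e-6)
    return ClinicalTable(pd.DataFrame({
        "patient_id": risk.index,
        "time": times,
        "event": events,
    }))


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
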