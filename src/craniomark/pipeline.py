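"""Three-phase inference, error evaluation and phase-comparison statistics.

Phase 1 regresses all 16 landmark coordinates from the compressed
whole-volume stack.  Phase 2 re-predicts each landmark from a
full-resolution window centered on the phase-1 (x, y); phase 3 repeats
with a half-width window centered on the phase-2 estimate.  Window
origins are recorded so local predictions remap exactly to the global
frame; the predicted z is always global and never moves the window.

Localization error is reported per axis (|dx|, |dy|, |dz|) and as the 3D
Euclidean distance d3 = sqrt(dx^2 + dy^2 + dz^2), in pixel units.  Phase
errors are compared with the Conover-Iman rank-based post-hoc test
(pairwise t statistics on rank sums after a Kruskal-Wallis step) with
Holm adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .cropper import (
    build_phase1_dataset,
    build_refinement_dataset,
    crop_stack,
    make_shift_grid,
    remap_to_global,
)
from .errors import ConfigurationError, InputError
from .landmarks import CODES, N_LANDMARKS, LandmarkTable
from .nets import (
    PHASE1_OUTPUTS,
    REFINE_OUTPUTS,
    Regressor,
    RegressorSpec,
    TrainingConfig,
    build_regressor,
    load_weights,
    train,
)
from .volume_io import CaseVolume, stack_from_config

logger = logging.getLogger(__name__)

PHASES = ("phase1", "phase2", "phase3")


@dataclass
class PredictionSet:
    """All three phases' predictions for one case, global px."""

    case_id: str
    phase1: np.ndarray  # (16, 3)
    phase2: np.ndarray
    phase3: np.ndarray
    windows2: list = field(default_factory=list)
    windows3: list = field(default_factory=list)

    def by_phase(self, phase: str) -> np.ndarray:
        return {"phase1": self.phase1, "phase2": self.phase2, "phase3": self.phase3}[phase]


@dataclass
class ModelBundle:
    """The 1 + 16 + 16 = 33 networks of a complete system."""

    phase1: Regressor
    phase2: dict[str, Regressor]
    phase3: dict[str, Regressor]

    def __post_init__(self) -> None:
        missing = [c for c in CODES if c not in self.phase2 or c not in self.phase3]
        if missing:
            raise ConfigurationError(f"missing refinement models for {missing}")

    @property
    def n_models(self) -> int:
        return 1 + len(self.phase2) + len(self.phase3)


def weight_file_names() -> list[str]:
    """Canonical names of the 33 weight files of a full run."""
    return (
        ["phase1.w"]
        + [f"phase2_{c}.w" for c in CODES]
        + [f"phase3_{c}.w" for c in CODES]
    )


def load_bundle(models_dir: str | Path) -> ModelBundle:
    models_dir = Path(models_dir)
    for name in weight_file_names():
        if not (models_dir / name).exists():
            raise ConfigurationError(f"missing model file {models_dir / name}")
    return ModelBundle(
        phase1=load_weights(models_dir / "phase1.w"),
        phase2={c: load_weights(models_dir / f"phase2_{c}.w") for c in CODES},
        phase3={c: load_weights(models_dir / f"phase3_{c}.w") for c in CODES},
    )


# ----------------------------------------------------------------------
# staged inference


def predict_phase1(model: Regressor, volume: CaseVolume, config: PipelineConfig) -> np.ndarray:
    """Whole-volume coarse prediction: 16 x (x, y, z) in global px."""
    if model.n_outputs != PHASE1_OUTPUTS:
        raise InputError(f"phase-1 model must have 48 outputs, has {model.n_outputs}")
    stack = stack_from_config(volume, config)
    vec = model.predict(stack.voxels[None])[0]
    return vec.reshape(N_LANDMARKS, 3).astype(np.float64)


def refine(
    volume: CaseVolume,
    prior: np.ndarray,
    landmark_code: str,
    width: int,
    model: Regressor,
    config: PipelineConfig,
    _bone: np.ndarray | None = None,
):
    """One refinement step: crop at the prior (x, y), predict, remap.

    Returns (global prediction, crop window).  The prior z propagates
    into nothing — the crop always spans the full z extent — and the
    predicted z is taken as global directly.
    """
    if model.n_outputs != REFINE_OUTPUTS:
        raise InputError("refinement model must have 3 outputs")
    stack, window = crop_stack(
        volume,
        (float(prior[0]), float(prior[1])),
        width,
        depth=config.depth,
        threshold=config.threshold,
        _bone=_bone,
    )
    local = model.predict(stack.voxels[None])[0].astype(np.float64)
    glob = remap_to_global(local, window)
    return glob, window


def run_full(
    volume: CaseVolume, models: ModelBundle, config: PipelineConfig
) -> PredictionSet:
    """Chain phase 1 -> phase 2 (width w2) -> phase 3 (width w3)."""
    from .cropper import _binary_volume

    p1 = predict_phase1(models.phase1, volume, config)
    bone = _binary_volume(volume, config.threshold)
    p2 = np.zeros_like(p1)
    p3 = np.zeros_like(p1)
    windows2, windows3 = [], []
    for i, code in enumerate(CODES):
        p2[i], w2 = refine(
            volume, p1[i], code, config.phase2_width, models.phase2[code], config, _bone=bone
        )
        p3[i], w3 = refine(
            volume, p2[i], code, config.phase3_width, models.phase3[code], config, _bone=bone
        )
        windows2.append(w2)
        windows3.append(w3)
    logger.info("case %s: three-phase prediction complete", volume.case_id)
    return PredictionSet(
        case_id=volume.case_id, phase1=p1, phase2=p2, phase3=p3,
        windows2=windows2, windows3=windows3,
    )


# ----------------------------------------------------------------------
# evaluation


@dataclass
class ErrorReport:
    """Per-observation localization errors plus pooled summaries.

    ``records`` has one row per (case, landmark, phase) with |dx|, |dy|,
    |dz| and d3 in px.  Summaries pool all case x landmark observations.
    """

    records: pd.DataFrame

    def summary_by_phase(self) -> pd.DataFrame:
        return self.records.groupby("phase")["d3"].agg(
            average="mean", median="median", stdev=lambda s: s.std(ddof=1)
        )

    def summary_by_landmark(self) -> pd.DataFrame:
        return self.records.groupby(["phase", "landmark"])["d3"].agg(
            average="mean", median="median", stdev=lambda s: s.std(ddof=1)
        )

    def summary_by_axis(self) -> pd.DataFrame:
        long = self.records.melt(
            id_vars=["phase"], value_vars=["dx", "dy", "dz"],
            var_name="axis", value_name="error",
        )
        return long.groupby(["phase", "axis"])["error"].agg(
            average="mean", median="median", stdev=lambda s: s.std(ddof=1)
        )

    def phase_errors(self, phase: str) -> np.ndarray:
        return self.records.loc[self.records["phase"] == phase, "d3"].to_numpy()

    def mean_d3(self, phase: str) -> float:
        return float(self.phase_errors(phase).mean())


def evaluate(preds: list[PredictionSet], truth: list[LandmarkTable]) -> ErrorReport:
    """Per-axis absolute gaps and 3D distances for every prediction."""
    truth_by_case = {t.case_id: t for t in truth}
    rows = []
    for ps in preds:
        if ps.case_id not in truth_by_case:
            raise InputError(f"no ground truth for case {ps.case_id!r}")
        gt = truth_by_case[ps.case_id].points
        for phase in PHASES:
            diff = ps.by_phase(phase) - gt
            d3 = np.linalg.norm(diff, axis=1)
            for i, code in enumerate(CODES):
                rows.append(
                    (ps.case_id, code, phase,
                     abs(diff[i, 0]), abs(diff[i, 1]), abs(diff[i, 2]), d3[i])
                )
    df = pd.DataFrame(rows, columns=["case_id", "landmark", "phase", "dx", "dy", "dz", "d3"])
    return ErrorReport(records=df)


# ----------------------------------------------------------------------
# Conover-Iman post-hoc comparison


def compare_groups(error_groups: list[np.ndarray], labels: list[str] | None = None,
                   p_adjust: str = "holm") -> pd.DataFrame:
    """Pairwise Conover-Iman test with Holm adjustment.

    After ranking the pooled observations, the statistic for groups i, j is

        t = (Rbar_i - Rbar_j) / sqrt(S^2 * (N-1-H)/(N-k) * (1/n_i + 1/n_j))

    with S^2 the tie-corrected variance of the ranks and H the
    Kruskal-Wallis statistic computed from rank sums; p-values come from
    a t distribution with N - k degrees of freedom.  Returns a symmetric
    k x k matrix of adjusted p-values with unit diagonal.
    """
    k = len(error_groups)
    if k < 2:
        raise InputError("need at least two groups")
    groups = [np.asarray(g, dtype=np.float64).ravel() for g in error_groups]
    if any(len(g) < 2 for g in groups):
        raise InputError("every group needs at least two observations")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]

    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = np.array([len(g) for g in groups])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rank_sums = np.array([ranks[bounds[i]:bounds[i + 1]].sum() for i in range(k)])
    rank_means = rank_sums / sizes

    s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    if s2 <= 0:  # all observations tied
        warnings.warn("all observations are tied; comparison is degenerate")
        return pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    h = (np.sum(rank_sums**2 / sizes) - n * (n + 1) ** 2 / 4.0) / s2
    df = n - k
    factor = s2 * (n - 1 - h) / df
    factor = max(factor, 1e-12)

    pmat = np.ones((k, k))
    raw, pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
            t = (rank_means[i] - rank_means[j]) / se
            raw.append(2.0 * stats.t.sf(abs(t), df))
            pairs.append((i, j))
    adj = _holm(np.array(raw)) if p_adjust == "holm" else np.minimum(np.array(raw), 1.0)
    for (i, j), p in zip(pairs, adj):
        pmat[i, j] = pmat[j, i] = p
    return pd.DataFrame(pmat, index=labels, columns=labels)


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


# ----------------------------------------------------------------------
# end-to-end training


def train_all(
    cases: list[CaseVolume],
    tables: list[LandmarkTable],
    config: PipelineConfig,
    out_dir: str | Path,
    seed: int = 0,
) -> ModelBundle:
    """Train the complete 33-network system and persist every weight file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    p1_spec = RegressorSpec.from_net_config(
        (config.phase1_size, config.phase1_size, config.depth),
        PHASE1_OUTPUTS, config.net, seed=seed,
    )
    p1_model = build_regressor(p1_spec)
    p1_data = build_phase1_dataset(
        cases, tables, width=config.phase1_size, depth=config.depth,
        threshold=config.threshold,
    )
    train(
        p1_model, p1_data,
        TrainingConfig(
            batch_size=config.phase1_training.batch_size,
            epochs=config.phase1_training.epochs,
            learning_rate=config.net.learning_rate, seed=seed,
        ),
        out_path=out_dir / "phase1.w",
    )
    logger.info("phase 1 trained (final loss %.4f)", p1_model.history[-1])

    bundles: dict[str, dict[str, Regressor]] = {"phase2": {}, "phase3": {}}
    for phase, width, shift, tc in (
        ("phase2", config.phase2_width, config.phase2_shift, config.phase2_training),
        ("phase3", config.phase3_width, config.phase3_shift, config.phase3_training),
    ):
        grid = make_shift_grid(*shift)
        for li, code in enumerate(CODES):
            spec = RegressorSpec.from_net_config(
                (width, width, config.depth), REFINE_OUTPUTS, config.net,
                seed=seed + 1000 * (1 + PHASES.index(phase)) + li,
            )
            model = build_regressor(spec)
            data = build_refinement_dataset(
                cases, tables, code, width, grid,
                depth=config.depth, threshold=config.threshold,
            )
            train(
                model, data,
                TrainingConfig(
                    batch_size=tc.batch_size, epochs=tc.epochs,
                    learning_rate=config.net.learning_rate,
                    seed=seed + 2000 * (1 + PHASES.index(phase)) + li,
                ),
                out_path=out_dir / f"{phase}_{code}.w",
            )
            bundles[phase][code] = model
            logger.info("%s %s trained (final loss %.4f)", phase, code, model.history[-1])
    return ModelBundle(phase1=p1_model, phase2=bundles["phase2"], phase3=bundles["phase3"])


# ----------------------------------------------------------------------
# prediction CSV I/O (landmark-table format plus a phase column)


def write_predictions(preds: list[PredictionSet], path: str | Path) -> None:
    rows = []
    for ps in preds:
        for phase in PHASES:
            pts = ps.by_phase(phase)
            for i, code in enumerate(CODES):
                rows.append((ps.case_id, phase, code, *pts[i]))
    pd.DataFrame(rows, columns=["case_id", "phase", "code", "x", "y", "z"]).to_csv(
        path, index=False
    )


def read_predictions(path: str | Path) -> list[PredictionSet]:
    df = pd.read_csv(path, dtype={"case_id": str})
    preds = []
    for case_id, grp in df.groupby("case_id", sort=False):
        arrays = {}
        for phase in PHASES:
            sub = grp[grp["phase"] == phase].set_index("code").loc[list(CODES)]
            arrays[phase] = sub[["x", "y", "z"]].to_numpy()
        preds.append(PredictionSet(case_id=str(case_id), **arrays))
    return preds


# ----------------------------------------------------------------------
# desk-scale phantom benchmark


def run_benchmark(
    seed: int = 0,
    n_train: int = 20,
    n_test: int = 10,
    config: PipelineConfig | None = None,
    models_dir: str | Path | None = None,
) -> dict:
    """Train and evaluate the full three-phase system on phantoms.

    Generates a fixed-seed phantom cohort, trains all 33 networks at the
    given configuration (desk scale by default), runs staged inference on
    the held-out cases and returns the error report, the Conover-Iman
    p-value matrix across phases, and the mean 3D error per phase.
    """
    import tempfile

    from .landmarks import split_train_test
    from .phantom import PhantomSpec, generate_cohort

    config = config or PipelineConfig.desk_scale()
    spec = PhantomSpec.desk_scale(seed=seed, n_cases=n_train + n_test)
    volumes, tables = generate_cohort(spec)
    by_id = {v.case_id: v for v in volumes}
    train_tables, test_tables = split_train_test(tables, n_train, n_test, seed=seed)
    train_vols = [by_id[t.case_id] for t in train_tables]
    test_vols = [by_id[t.case_id] for t in test_tables]

    if models_dir is None:
        models_dir = tempfile.mkdtemp(prefix="craniomark_models_")
    bundle = train_all(train_vols, train_tables, config, models_dir, seed=seed)

    preds = [run_full(v, bundle, config) for v in test_vols]
    report = evaluate(preds, test_tables)
    groups = [report.phase_errors(p) for p in PHASES]
    pvals = compare_groups(groups, labels=list(PHASES))
    means = {p: report.mean_d3(p) for p in PHASES}
    logger.info(
        "benchmark means: phase1 %.2f px, phase2 %.2f px, phase3 %.2f px",
        means["phase1"], means["phase2"], means["phase3"],
    )
    return {
        "report": report,
        "p_values": pvals,
        "means": means,
        "bundle": bundle,
        "models_dir": Path(models_dir),
        "predictions": preds,
        "test_tables": test_tables,
    }
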