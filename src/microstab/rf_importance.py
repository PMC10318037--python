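"""Tuned random-forest regression with dataset-shuffle permutation importance.

Each ecosystem function is regressed on candidate microbial predictors
(alpha diversity, community-membership PCoA scores, abundance metrics,
life-history and taxonomic indicators) with a bagged forest. "Model error"
is always out-of-bag (OOB): each sample is predicted only by trees whose
bootstrap sample excluded it — in-bag evaluation would reward overfitting
and make every predictor look informative. The forest is tuned over the
number of candidate predictors per split (1..P) to minimize OOB mean
squared error, and a predictor's importance is the mean increase in OOB
MSE after shuffling that predictor's column across the data set, holding
all other columns fixed.

The forest learner is scikit-learn's; the OOB bookkeeping, tuning loop,
and shuffle-importance procedure live here. OOB membership per tree is
reconstructed from each tree's bootstrap stream, which matches the
learner's own OOB predictions exactly (asserted in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from ._util import substream_rng

#: Base candidate predictors offered to every model.
BASE_PREDICTORS = (
    "richness",
    "shannon",
    "biomass",
    "dna_yield",
    "abund_16s",
    "mean_operon_number",
    "tetw",
    "tetm",
    "proteo_actino_ratio",
)

#: Extra predictors offered only to the nitrification model.
NITRIFIER_PREDICTORS = ("aoa", "aob")


@dataclass
class RFConfig:
    n_trees: int = 10_000
    n_shuffles: int = 30
    seed: int = 0
    variant: str = "primary"  # or "alternative" (adds responder-genus abundances)
    n_axes: int = 3

    def __post_init__(self) -> None:
        if self.n_trees < 100:
            raise ValueError("n_trees must be >= 100")
        if self.variant not in ("primary", "alternative"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class PredictorInputs:
    """Per-sample source frames joined on sample id during assembly."""

    diversity: pd.DataFrame  # columns richness, shannon
    ordination: pd.DataFrame  # columns PCoA1..k
    composition: pd.DataFrame  # proteo_actino_ratio, mean_operon_number, genus_* (optional)
    covariates: pd.DataFrame  # biomass, dna_yield, abund_16s, tetw, tetm, aoa, aob


@dataclass
class ImportanceResult:
    response: str
    table: pd.DataFrame  # per predictor: raw_importance, importance, rank
    tuned_max_features: int
    oob_mse: float
    tuning_trace: pd.DataFrame
    n_trees: int
    n_shuffles: int
    seed: int


def assemble_predictors(
    inputs: PredictorInputs,
    response_name: str,
    y: pd.Series,
    variant: str = "primary",
    n_axes: int = 3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Build the response-specific predictor matrix.

    Nitrifier abundances (AOA, AOB) are offered only when the response is
    nitrification; responder-genus relative abundances only in the
    ``"alternative"`` variant. Zero-variance columns are dropped with a
    warning; rows with any missing value are dropped.
    """
    pieces = [
        inputs.diversity[["richness", "shannon"]],
        inputs.ordination.iloc[:, : min(n_axes, inputs.ordination.shape[1])],
        inputs.covariates[[c for c in ("biomass", "dna_yield", "abund_16s", "tetw", "tetm") if c in inputs.covariates]],
        inputs.composition[[c for c in ("mean_operon_number", "proteo_actino_ratio") if c in inputs.composition]],
    ]
    if response_name == "nitrification":
        pieces.append(inputs.covariates[[c for c in NITRIFIER_PREDICTORS if c in inputs.covariates]])
    if variant == "alternative":
        genus_cols = [c for c in inputs.composition.columns if c.startswith("genus_")]
        pieces.append(inputs.composition[genus_cols])
    x = pd.concat(pieces, axis=1, join="inner")
    frame = x.join(y.rename("__response__"), how="inner").dropna()
    if len(frame) < 10:
        raise ValueError(f"only {len(frame)} complete rows for {response_name!r}; need >= 10")
    y_out = frame.pop("__response__")
    const = frame.columns[frame.nunique() <= 1]
    if len(const):
        warnings.warn(f"dropping constant predictor(s): {const.tolist()}")
        frame = frame.drop(columns=const)
    return frame, y_out


# ---------------------------------------------------------------------------
# OOB machinery
# ---------------------------------------------------------------------------


def _oob_masks(model: RandomForestRegressor, n: int) -> np.ndarray:
    """Boolean (n_trees, n) matrix: True where a sample is OOB for a tree.

    Reconstructs each tree's in-bag multiset from its bootstrap stream
    (``randint(0, n, n)`` on the tree's random state), the draw the
    learner itself makes when bagging.
    """
    masks = np.ones((len(model.estimators_), n), dtype=bool)
    for t, tree in enumerate(model.estimators_):
        inbag = np.random.RandomState(tree.random_state).randint(0, n, n)
        masks[t, inbag] = False
    return masks


def _oob_predictions(model: RandomForestRegressor, X: np.ndarray, masks: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for t, tree in enumerate(model.estimators_):
        m = masks[t]
        if m.any():
            acc[m] += tree.predict(X[m], check_input=False)
            cnt[m] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)


def oob_mse(model: RandomForestRegressor, X, y, masks: np.ndarray | None = None) -> float:
    """Out-of-bag mean squared error, over samples with >= 1 OOB tree."""
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=float)
    if masks is None:
        masks = _oob_masks(model, len(y))
    pred = _oob_predictions(model, X, masks)
    ok = ~np.isnan(pred)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} sample(s) with no OOB trees excluded from OOB error")
    return float(np.mean((pred[ok] - y[ok]) ** 2))


# ---------------------------------------------------------------------------
# Tuning and importance
# ---------------------------------------------------------------------------


def tune_and_fit(
    X: pd.DataFrame, y: pd.Series, n_trees: int = 10_000, seed: int = 0, grid=None
) -> tuple[RandomForestRegressor, pd.DataFrame]:
    """Fit forests over a candidates-per-split grid and keep the OOB argmin.

    The grid defaults to 1..P. Ties break toward the smallest value.
    """
    yv = np.asarray(y, dtype=float)
    if np.ptp(yv) == 0:
        raise ValueError("response is constant")
    p = X.shape[1]
    grid = list(grid) if grid is not None else list(range(1, p + 1))
    xv = np.asarray(X, dtype=np.float32)
    trace = []
    best = None
    for m in grid:
        model = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=m,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        ).fit(xv, yv)
        err = oob_mse(model, xv, yv)
        trace.append((m, err))
        if best is None or err < best[1]:
            best = (m, err, model)
    trace_df = pd.DataFrame(trace, columns=["max_features", "oob_mse"])
    best[2].tuned_max_features_ = best[0]
    return best[2], trace_df


def permutation_importance(
    model: RandomForestRegressor,
    X: pd.DataFrame,
    y: pd.Series,
    n_shuffles: int = 30,
    seed: int = 0,
    response: str = "response",
    tuning_trace: pd.DataFrame | None = None,
) -> ImportanceResult:
    """Dataset-shuffle permutation importance evaluated out-of-bag.

    For each predictor, the column is independently permuted ``n_shuffles``
    times (all other columns fixed) and the OOB MSE recomputed; importance
    is the mean error increase over the unshuffled baseline. Raw values are
    retained; the ranked report clamps negative means to zero.
    """
    xv = np.asarray(X, dtype=np.float32)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    masks = _oob_masks(model, n)
    baseline = oob_mse(model, xv, yv, masks)
    raw = {}
    for j, col in enumerate(X.columns):
        deltas = np.empty(n_shuffles)
        for k in range(n_shuffles):
            rng = substream_rng(seed, "shuffle", col, k)
            xp = xv.copy()
            xp[:, j] = xp[rng.permutation(n), j]
            deltas[k] = oob_mse(model, xp, yv, masks) - baseline
        raw[col] = deltas.mean()
    raw_s = pd.Series(raw, name="raw_importance")
    order = np.lexsort((np.arange(len(raw_s)), -raw_s.to_numpy()))
    ranks = np.empty(len(raw_s), dtype=int)
    ranks[order] = np.arange(1, len(raw_s) + 1)
    table = pd.DataFrame(
        {
            "raw_importance": raw_s,
            "importance": raw_s.clip(lower=0.0),
            "rank": ranks,
        }
    ).sort_values("rank")
    table.index.name = "predictor"
    return ImportanceResult(
        response=response,
        table=table,
        tuned_max_features=getattr(model, "tuned_max_features_", model.max_features),
        oob_mse=baseline,
        tuning_trace=tuning_trace if tuning_trace is not None else pd.DataFrame(),
        n_trees=model.n_estimators,
        n_shuffles=n_shuffles,
        seed=seed,
    )


def run_all_models(
    functions: pd.DataFrame,
    inputs: PredictorInputs,
    config: RFConfig = RFConfig(),
) -> dict[str, ImportanceResult]:
    """One tuned-forest importance model per function column.

    ``functions`` should contain the six process rates plus the
    multifunctionality column. Failures of individual responses are
    isolated with a warning so the run continues.
    """
    results: dict[str, ImportanceResult] = {}
    for response in functions.columns:
        try:
            x, yy = assemble_predictors(
                inputs, response, functions[response], variant=config.variant, n_axes=config.n_axes
            )
            model, trace = tune_and_fit(x, yy, n_trees=config.n_trees, seed=config.seed)
            results[response] = permutation_importance(
                model, x, yy,
                n_shuffles=config.n_shuffles, seed=config.seed,
                response=response, tuning_trace=trace,
            )
        except Exception as exc:  # noqa: BLE001 - isolate per-response failures
            warnings.warn(f"model for {response!r} failed: {exc}")
    return results


def top_predictors(result: ImportanceResult, k: int = 6) -> pd.DataFrame:
    """Top-k ranked predictors (the conventional reporting cut)."""
    return result.table.head(k)
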