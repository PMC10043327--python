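"""Covariate-adjusted multifactor dimensionality reduction (generalized MDR).

Classic MDR pools the cells of a k-SNP genotype table into HIGH- and
LOW-risk classes by comparing each cell's case:control ratio with the
cohort ratio.  The generalized form used here replaces counts with score
residuals s_i = y_i - p_i from a covariates-only logistic null model: a
cell is HIGH risk when its residual sum is positive.  With an empty
covariate set the two labelings coincide exactly.

Model search evaluates every k-SNP combination by training balanced
accuracy within each cross-validation fold, reports the modal fold winner,
its mean testing balanced accuracy (TBA) over the folds it won, and the
cross-validation consistency (CVC).  The search is repeated under several
derived seeds and the most frequently identified model is selected, with
ties broken by TBA, then CVC, then testing specificity.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotype_io import MISSING, GenotypeMatrix
from .network_panel import SnpPanel, iter_combinations

log = logging.getLogger(__name__)

HIGH, LOW, EMPTY = 1, 0, -1

DEFAULT_COVARIATES = ("stage", "location", "chemo", "radio")

#: residual sums within this margin of the threshold count as exact ties
#: (labeled LOW); absorbs float rounding of sums that are algebraically zero
TIE_ATOL = 1e-9

#: combos are processed in blocks to bound the (n_samples x n_combos)
#: cell-index matrix at roughly 100 MB regardless of panel size
_COMBO_BLOCK = 20_000


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the cross-validated exhaustive search."""

    k: int
    folds: int = 5
    repeats: int = 20
    seed: int = 0
    risk_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class ScoreVector:
    """Per-sample score residuals from the covariates-only null model."""

    scores: np.ndarray
    params: pd.Series
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if abs(self.scores.sum()) > 1e-6 * max(1, len(self.scores)):
            warnings.warn("score residuals do not sum to zero; null fit may be degraded")


@dataclass
class CellPartition:
    """Genotype-cell decomposition of a SNP combination on a training set."""

    combo: tuple[str, ...]
    counts: np.ndarray  # (3^k,) training occupancy
    score_sums: np.ndarray  # (3^k,) training residual sums
    labels: np.ndarray  # (3^k,) HIGH/LOW/EMPTY

    @property
    def k(self) -> int:
        return len(self.combo)


@dataclass
class MdrModel:
    """A selected k-SNP model with its cross-validation statistics."""

    combo: tuple[str, ...]
    k: int
    train_ba: float
    tba: float
    sensitivity: float
    specificity: float
    cvc: int
    folds: int
    fold_winners: list[tuple[str, ...]]
    cell_labels: np.ndarray  # (3^k,) full-data HIGH/LOW/EMPTY
    cell_counts: np.ndarray
    cell_score_sums: np.ndarray


# ---------------------------------------------------------------------------
# null-model scores
# ---------------------------------------------------------------------------

def build_design(samples: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Design matrix for the adjustment set.

    Encodings: stage as dummies with reference I, location with reference
    colon, chemo/radio as 0/1 indicators.
    """
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "stage":
            cols["stage_II"] = (samples["stage"] == "II").to_numpy(float)
            cols["stage_III"] = (samples["stage"] == "III").to_numpy(float)
        elif cov == "location":
            cols["location_rectum"] = (samples["location"] == "rectum").to_numpy(float)
        elif cov in ("chemo", "radio"):
            cols[cov] = samples[cov].to_numpy(float)
        else:
            cols[cov] = samples[cov].to_numpy(float)
    design = pd.DataFrame(cols, index=samples.index)
    design.insert(0, "intercept", 1.0)
    return design


def compute_scores(
    samples: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> ScoreVector:
    """Fit outcome ~ covariates by ML logistic regression; return y - p_hat.

    With an empty covariate set this reduces to y_i - mean(y).  Complete
    separation triggers a ridge-stabilized refit with a warning.
    """
    y = samples["status5y"].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("status5y must be complete for every sample entering MDR")
    if y.min() == y.max():
        raise ValueError("outcome is constant: null model degenerate")
    X = build_design(samples, covariates)
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200, tol=1e-12)
        params = res.params
        converged = res.mle_retvals.get("converged", True)
        if not converged or np.abs(params.to_numpy()).max() > 30:
            raise np.linalg.LinAlgError("suspect separation")
    except Exception:
        warnings.warn("logistic null model unstable (separation?); ridge-stabilized fit used")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=0, maxiter=500)
        params = res.params
    p_hat = model.predict(params)
    scores = y - np.asarray(p_hat)
    ids = samples["sample_id"].tolist() if "sample_id" in samples.columns else [
        str(i) for i in range(len(y))
    ]
    return ScoreVector(scores=scores, params=pd.Series(params, index=X.columns), sample_ids=ids)


# ---------------------------------------------------------------------------
# cells and balanced accuracy (single-combo reference path)
# ---------------------------------------------------------------------------

def _cell_index_single(matrix: GenotypeMatrix, combo: Sequence[str]) -> np.ndarray:
    idx = np.zeros(matrix.n_samples, dtype=np.int64)
    for j, snp in enumerate(combo):
        col = matrix.column(snp)
        if (col == MISSING).any():
            raise ValueError(f"MISSING dosage in {snp}: run QC first")
        idx += col.astype(np.int64) * 3**j
    return idx


def partition_cells(
    combo: Sequence[str],
    matrix: GenotypeMatrix,
    scores: ScoreVector,
    train_idx: Sequence[int],
    threshold: float = 0.0,
) -> CellPartition:
    """Label each genotype cell HIGH/LOW by its training residual sum.

    HIGH iff sum > threshold; LOW on exact tie (logged); unobserved cells
    are EMPTY.
    """
    combo = tuple(combo)
    k = len(combo)
    n_cells = 3**k
    cell_idx = _cell_index_single(matrix, combo)[list(train_idx)]
    s = scores.scores[list(train_idx)]
    counts = np.bincount(cell_idx, minlength=n_cells).astype(np.int64)
    sums = np.bincount(cell_idx, weights=s, minlength=n_cells)
    labels = np.where(sums > threshold + TIE_ATOL, HIGH, LOW).astype(np.int8)
    ties = (counts > 0) & (np.abs(sums - threshold) <= TIE_ATOL)
    if ties.any():
        log.info("combo %s: %d exact-tie cells labeled LOW", combo, int(ties.sum()))
    labels[counts == 0] = EMPTY
    return CellPartition(combo=combo, counts=counts, score_sums=sums, labels=labels)


def balanced_accuracy(
    partition: CellPartition,
    scores: ScoreVector,
    eval_idx: Sequence[int],
    matrix: GenotypeMatrix,
) -> tuple[float, float, float]:
    """(BA, sensitivity, specificity) of a fitted partition on eval samples.

    Truth is the sign of the score residual (positive = case under the null
    model); a sample predicts HIGH iff its cell is labeled HIGH, with EMPTY
    cells predicting LOW.
    """
    eval_idx = list(eval_idx)
    if not eval_idx:
        raise ValueError("empty evaluation set")
    s = scores.scores[eval_idx]
    truth = s > 0
    if truth.all() or (~truth).all():
        raise ValueError("evaluation set lacks one truth class: BA undefined")
    cell_idx = _cell_index_single(matrix, partition.combo)[eval_idx]
    pred = partition.labels[cell_idx] == HIGH
    tp = int(np.sum(pred & truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return (sens + spec) / 2.0, sens, spec


# ---------------------------------------------------------------------------
# vectorized multi-combo evaluation
# ---------------------------------------------------------------------------

def _combo_columns(matrix: GenotypeMatrix, combos: Sequence[tuple[str, ...]]) -> np.ndarray:
    return np.array(
        [[matrix.column_index(s) for s in combo] for combo in combos], dtype=np.int32
    )


def _cell_indices_block(dosage: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """(n_samples, m) cell index for m combos; cols is (m, k) column indices."""
    k = cols.shape[1]
    out = dosage[:, cols[:, 0]].astype(np.int32)
    for j in range(1, k):
        out += dosage[:, cols[:, j]].astype(np.int32) * 3**j
    return out


def _evaluate_block(
    cell_idx: np.ndarray,
    scores: np.ndarray,
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    n_cells: int,
    threshold: float = 0.0,
) -> dict[str, np.ndarray]:
    """Train/test balanced accuracy for every combo in a block at once.

    Cells unseen in training carry zero residual sum and therefore predict
    LOW, matching the EMPTY-cell rule of the reference path.
    """
    n, m = cell_idx.shape
    offsets = np.arange(m, dtype=np.int64) * n_cells
    flat = cell_idx.astype(np.int64) + offsets[None, :]
    minlength = m * n_cells
    pos = scores > 0

    tr_flat = flat[train_mask].ravel()
    n_tr = int(train_mask.sum())
    w_scores = np.broadcast_to(scores[train_mask, None], (n_tr, m)).ravel()
    w_pos = np.broadcast_to(pos[train_mask, None], (n_tr, m)).ravel().astype(float)
    sums = np.bincount(tr_flat, weights=w_scores, minlength=minlength).reshape(m, n_cells)
    npos_tr = np.bincount(tr_flat, weights=w_pos, minlength=minlength).reshape(m, n_cells)
    ntot_tr = np.bincount(tr_flat, minlength=minlength).reshape(m, n_cells)
    nneg_tr = ntot_tr - npos_tr
    high = sums > threshold + TIE_ATOL  # exact tie -> LOW

    P_tr = float(pos[train_mask].sum())
    N_tr = float(n_tr - P_tr)
    tp_tr = (npos_tr * high).sum(axis=1)
    tn_tr = (nneg_tr * ~high).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        train_ba = 0.5 * (tp_tr / P_tr + tn_tr / N_tr)

    out = {"train_ba": train_ba, "high": high}
    if test_mask is not None and test_mask.any():
        te_flat = flat[test_mask].ravel()
        n_te = int(test_mask.sum())
        w_pos_te = np.broadcast_to(pos[test_mask, None], (n_te, m)).ravel().astype(float)
        npos_te = np.bincount(te_flat, weights=w_pos_te, minlength=minlength).reshape(m, n_cells)
        ntot_te = np.bincount(te_flat, minlength=minlength).reshape(m, n_cells)
        nneg_te = ntot_te - npos_te
        P_te = float(pos[test_mask].sum())
        N_te = float(n_te - P_te)
        tp_te = (npos_te * high).sum(axis=1)
        tn_te = (nneg_te * ~high).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sens = tp_te / P_te
            spec = tn_te / N_te
            out["test_ba"] = 0.5 * (sens + spec)
        out["test_sens"] = sens
        out["test_spec"] = spec
    return out


# ---------------------------------------------------------------------------
# cross-validation machinery
# ---------------------------------------------------------------------------

def make_folds(strata: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold labels, stratified so each fold mirrors the class split."""
    n = len(strata)
    fold = np.empty(n, dtype=np.int32)
    for value in np.unique(strata):
        idx = np.flatnonzero(strata == value)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def run_cv(
    combo: Sequence[str],
    matrix: GenotypeMatrix,
    scores: ScoreVector,
    config: SearchConfig,
) -> pd.DataFrame:
    """Per-fold train/test statistics for a single fixed combination."""
    combo = tuple(combo)
    if matrix.n_samples < config.folds:
        raise ValueError("fewer samples than folds")
    rng = np.random.default_rng(config.seed)
    strata = scores.scores > 0
    fold = make_folds(strata, config.folds, rng)
    rows = []
    for f in range(config.folds):
        train_idx = np.flatnonzero(fold != f)
        test_idx = np.flatnonzero(fold == f)
        part = partition_cells(combo, matrix, scores, train_idx, config.risk_threshold)
        tr_ba, _, _ = balanced_accuracy(part, scores, train_idx, matrix)
        try:
            te_ba, sens, spec = balanced_accuracy(part, scores, test_idx, matrix)
        except ValueError:
            warnings.warn(f"fold {f}: single truth class in test part, TBA undefined")
            te_ba = sens = spec = np.nan
        rows.append((f, tr_ba, te_ba, sens, spec))
    return pd.DataFrame(rows, columns=["fold", "train_ba", "test_ba", "sensitivity", "specificity"])


def search_k(
    panel: SnpPanel,
    matrix: GenotypeMatrix,
    scores: ScoreVector,
    config: SearchConfig,
) -> MdrModel:
    """Exhaustive cross-validated search over all k-tuples of a panel.

    In every training fold each combination is scored by training balanced
    accuracy (ties broken to the lexicographically first combination); the
    fold winner is evaluated on the held-out part.  The reported model is
    the modal fold winner; its TBA/sensitivity/specificity are means over
    the folds it won and CVC counts those folds.
    """
    if panel.size < config.k:
        raise ValueError(f"panel {panel.network} smaller than k={config.k}")
    combos = list(iter_combinations(panel, config.k))
    cols = _combo_columns(matrix, combos)
    n_cells = 3**config.k
    s = scores.scores
    rng = np.random.default_rng(config.seed)
    fold = make_folds(s > 0, config.folds, rng)

    winner_per_fold: list[int] = []
    fold_stats: list[tuple[float, float, float, float]] = []
    for f in range(config.folds):
        train_mask = fold != f
        test_mask = fold == f
        best_idx, best_ba = -1, -np.inf
        for start in range(0, len(combos), _COMBO_BLOCK):
            block_cols = cols[start : start + _COMBO_BLOCK]
            cell_idx = _cell_indices_block(matrix.dosage, block_cols)
            res = _evaluate_block(cell_idx, s, train_mask, None, n_cells,
                                  config.risk_threshold)
            j = int(np.argmax(res["train_ba"]))  # first max = lexicographic tie-break
            if res["train_ba"][j] > best_ba:
                best_ba, best_idx = float(res["train_ba"][j]), start + j
        cell_idx = _cell_indices_block(matrix.dosage, cols[best_idx : best_idx + 1])
        res = _evaluate_block(cell_idx, s, train_mask, test_mask, n_cells,
                              config.risk_threshold)
        winner_per_fold.append(best_idx)
        fold_stats.append(
            (best_ba, float(res["test_ba"][0]), float(res["test_sens"][0]),
             float(res["test_spec"][0]))
        )

    counts = Counter(winner_per_fold)
    top_freq = max(counts.values())
    modal_idx = min(i for i, c in counts.items() if c == top_freq)  # lexicographic
    modal_folds = [f for f, w in enumerate(winner_per_fold) if w == modal_idx]
    stats = np.array([fold_stats[f] for f in modal_folds], dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        train_ba = float(np.nanmean(stats[:, 0]))
        tba = float(np.nanmean(stats[:, 1]))
        sens = float(np.nanmean(stats[:, 2]))
        spec = float(np.nanmean(stats[:, 3]))
    if np.isnan(stats[:, 1]).any():
        warnings.warn("some winning folds had undefined TBA; excluded from the mean")

    combo = combos[modal_idx]
    full = partition_cells(combo, matrix, scores, np.arange(matrix.n_samples),
                           config.risk_threshold)
    return MdrModel(
        combo=combo,
        k=config.k,
        train_ba=train_ba,
        tba=tba,
        sensitivity=sens,
        specificity=spec,
        cvc=len(modal_folds),
        folds=config.folds,
        fold_winners=[combos[w] for w in winner_per_fold],
        cell_labels=full.labels,
        cell_counts=full.counts,
        cell_score_sums=full.score_sums,
    )


def repeat_and_select(
    panel: SnpPanel,
    matrix: GenotypeMatrix,
    scores: ScoreVector,
    config: SearchConfig,
) -> tuple[MdrModel, pd.DataFrame]:
    """Repeat the search under derived seeds and select the top model.

    Repeat r uses seed ``config.seed + r``.  Candidates are ranked by
    identification frequency, then mean TBA, then mean CVC, then mean
    testing specificity; remaining ties go to the lexicographically first
    combination.  The returned model is the best-TBA instance of the
    selected combination; the trace records every repeat's winner.
    """
    results: list[MdrModel] = []
    for r in range(config.repeats):
        cfg = SearchConfig(
            k=config.k, folds=config.folds, repeats=1,
            seed=config.seed + r, risk_threshold=config.risk_threshold,
        )
        results.append(search_k(panel, matrix, scores, cfg))
    trace = pd.DataFrame(
        {
            "repeat": range(config.repeats),
            "combo": [",".join(m.combo) for m in results],
            "tba": [m.tba for m in results],
            "cvc": [m.cvc for m in results],
            "sensitivity": [m.sensitivity for m in results],
            "specificity": [m.specificity for m in results],
        }
    )
    groups: dict[tuple[str, ...], list[MdrModel]] = {}
    for m in results:
        groups.setdefault(m.combo, []).append(m)

    def rank(item: tuple[tuple[str, ...], list[MdrModel]]):
        combo, ms = item
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return (
                -len(ms),
                -np.nanmean([m.tba for m in ms]),
                -np.mean([m.cvc for m in ms]),
                -np.nanmean([m.specificity for m in ms]),
                combo,
            )

    best_combo, best_models = min(groups.items(), key=rank)
    selected = max(best_models, key=lambda m: (np.nan_to_num(m.tba), m.cvc))
    return selected, trace


def iterative_oneway(
    panel: SnpPanel,
    matrix: GenotypeMatrix,
    scores: ScoreVector,
    config: SearchConfig,
    alpha: float = 0.001,
    B: int = 1000,
) -> list[tuple[MdrModel, float]]:
    """Iterative main-effect discovery.

    Repeatedly select the top 1-way model, permutation-test it, and if
    significant remove its SNP from the panel; stop at the first
    non-significant model.  Returns (model, p) pairs in discovery order.
    """
    from .permutation import permutation_pvalue

    found: list[tuple[MdrModel, float]] = []
    remaining = SnpPanel(panel.network, list(panel.snp_ids), dict(panel.snp_to_gene))
    round_no = 0
    while remaining.size >= 1:
        cfg = SearchConfig(
            k=1, folds=config.folds, repeats=config.repeats,
            seed=config.seed + 1_000_003 * round_no,
            risk_threshold=config.risk_threshold,
        )
        model, _ = repeat_and_select(remaining, matrix, scores, cfg)
        perm = permutation_pvalue(remaining, matrix, scores, cfg, B=B, observed=model)
        if perm.p_value < alpha:
            found.append((model, perm.p_value))
            keep = [s for s in remaining.snp_ids if s not in model.combo]
            remaining = SnpPanel(
                remaining.network, keep,
                {s: remaining.snp_to_gene.get(s, []) for s in keep},
            )
            round_no += 1
        else:
            break
    return found
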