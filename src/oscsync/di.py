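"""Directed-information functional connectivity from binary spike trains.

Each target unit Y is modeled with lasso-penalized logistic regressions
of its 1 ms-binned activity on summed-history features of its own past
(a refractory term Y(t-1)+Y(t-2) and a self-history term
Y(t-3)+...+Y(t-10)) and of candidate pre-synaptic units
(X(t-1)+...+X(t-10); Markov order 10 ms to limit confounding by slower
common inputs).  Directed information is the held-out average log2
likelihood ratio between a model with candidates and the self-only
model,

    I = (1/T) sum_t log2 [ P_full(Y(t) | features) / P_none(Y(t) | self) ],

normalized by the empirical binary entropy of Y on the same test rows,
so it reads as the fraction of uncertainty in Y removed by the
candidate set.  The total is attributed to the two source areas by the
two-player Shapley value, and area-level condition differences are
assessed per SF/TF stimulus with Monte-Carlo permutation tests and
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .core import Session, StimulusGrid
from .stats import fdr_bh, perm_test_median_diff

#: analysis window within the trial, seconds (stimulus onset to 1 s after)
DI_WINDOW = (0.5, 1.5)
BIN_S = 0.001
MARKOV_ORDER = 10       # bins of history per candidate unit
REFRACTORY_BINS = 2
IMBALANCE_LOOKBACK = 100  # bins
#: the 20-point lasso penalty grid, log-spaced over 1e-2..1e1
LAMBDA_GRID = tuple(np.logspace(-2, 1, 20))


class DegenerateModelError(ValueError):
    """Training rows contain a single response class; unit excluded."""


def summed_history(trains: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """X(t-lo) + ... + X(t-hi) along the last axis, zero-padded history.

    Shared between the generative sampler and the regression features so
    recovery tests have no model mismatch.
    """
    trains = np.asarray(trains)
    c = np.cumsum(trains, axis=-1, dtype=np.int64)
    n = trains.shape[-1]
    out = np.zeros(trains.shape, dtype=np.int64)
    for t in range(n):
        a, b = t - hi, t - lo
        if b < 0:
            continue
        upper = c[..., b]
        lower = c[..., a - 1] if a >= 1 else 0
        out[..., t] = upper - lower
    return out


@dataclass
class DIDataset:
    """Binary response rows and summed-history features for one target.

    Feature columns: refractory, self-history, then one per candidate in
    ``candidates`` order.  Rows come only from the post-onset analysis
    window, never from the first ``MARKOV_ORDER`` bins of a trial, and
    satisfy the imbalance rule (a row is dropped iff the target and every
    mask unit are silent at t and throughout the preceding 100 ms).
    """

    y: np.ndarray              # (n_rows,) uint8
    X: np.ndarray              # (n_rows, 2 + n_candidates) int
    target: object
    candidates: list
    trial_index: np.ndarray    # (n_rows,)
    stimulus_id: np.ndarray    # (n_rows,)
    bin_index: np.ndarray      # (n_rows,) bin within trial

    @property
    def n_rows(self) -> int:
        return self.y.size

    def columns_for(self, candidate_subset) -> np.ndarray:
        """Feature matrix restricted to refractory+self+a candidate subset."""
        cols = [0, 1] + [2 + self.candidates.index(c) for c in candidate_subset]
        return self.X[:, cols]

    def take(self, rows) -> "DIDataset":
        rows = np.asarray(rows)
        return DIDataset(
            self.y[rows], self.X[rows], self.target, self.candidates,
            self.trial_index[rows], self.stimulus_id[rows], self.bin_index[rows],
        )


def build_dataset_from_binary(
    trains: np.ndarray,
    target: int,
    candidates,
    stimulus_ids=None,
    mask_units=None,
) -> DIDataset:
    """Build a DI dataset from already-binarized trains.

    Parameters
    ----------
    trains : ndarray, (n_trials, n_units, n_bins) of {0, 1}
        1 ms-binned activity restricted to the analysis window.
    target : int
        Unit index of Y.
    candidates : sequence of int
        Candidate pre-synaptic unit indices (may be empty only when the
        dataset is meant for the self-only model).
    mask_units : sequence of int, optional
        Units the imbalance rule is evaluated against (default: the
        candidates).  Passing the full candidate set here for every
        sub-model keeps the row set identical across models, which the
        likelihood-ratio comparison requires.
    """
    trains = np.asarray(trains, dtype=np.uint8)
    n_trials, n_units, n_bins = trains.shape
    candidates = list(candidates)
    if target in candidates:
        raise ValueError("target must not appear among candidates")
    mask_units = candidates if mask_units is None else list(mask_units)

    y_tr = trains[:, target, :]
    group = trains[:, [target] + mask_units, :].max(axis=1)  # any activity
    # recent activity: any spike of Y or mask units in (t-100, t)
    recent = summed_history(group, 1, IMBALANCE_LOOKBACK) > 0
    keep = (group.astype(bool) | recent)
    keep[:, :MARKOV_ORDER] = False

    refr = summed_history(y_tr, 1, REFRACTORY_BINS)
    selfh = summed_history(y_tr, REFRACTORY_BINS + 1, MARKOV_ORDER)
    cand_feats = [
        summed_history(trains[:, c, :], 1, MARKOV_ORDER) for c in candidates
    ]

    tr_idx, bin_idx = np.nonzero(keep)
    X = np.column_stack(
        [refr[tr_idx, bin_idx], selfh[tr_idx, bin_idx]]
        + [cf[tr_idx, bin_idx] for cf in cand_feats]
    )
    if stimulus_ids is None:
        stim = np.zeros(n_trials, dtype=np.int64)
    else:
        stim = np.asarray(stimulus_ids, dtype=np.int64)
    return DIDataset(
        y=y_tr[tr_idx, bin_idx],
        X=X,
        target=target,
        candidates=candidates,
        trial_index=tr_idx,
        stimulus_id=stim[tr_idx],
        bin_index=bin_idx,
    )


def binarize_session(session: Session, unit_ids, window: tuple = DI_WINDOW) -> np.ndarray:
    """1 ms-bin spike trains of the given units within the analysis window."""
    n_bins = int(round((window[1] - window[0]) / BIN_S))
    out = np.zeros((session.n_trials, len(unit_ids), n_bins), dtype=np.uint8)
    for u, uid in enumerate(unit_ids):
        for tr, tt in enumerate(session.spike_trains[uid]):
            tt = np.asarray(tt, dtype=float)
            tt = tt[(tt >= window[0]) & (tt < window[1])]
            idx = np.minimum(((tt - window[0]) / BIN_S).astype(int), n_bins - 1)
            out[tr, u, idx] = 1
    return out


def build_dataset(
    session: Session, target, candidates, window: tuple = DI_WINDOW, mask_units=None
) -> DIDataset:
    """Binarize a session and build the DI dataset for one target unit."""
    unit_ids = [target] + [c for c in candidates if c != target]
    extra = [m for m in (mask_units or []) if m not in unit_ids]
    all_ids = unit_ids + extra
    trains = binarize_session(session, all_ids, window)
    cand_idx = [all_ids.index(c) for c in candidates]
    mask_idx = [all_ids.index(m) for m in mask_units] if mask_units else None
    ds = build_dataset_from_binary(
        trains, 0, cand_idx,
        stimulus_ids=session.trials["stimulus_id"].to_numpy(),
        mask_units=mask_idx,
    )
    ds.target = target
    ds.candidates = list(candidates)
    return ds


def split_train_test(dataset: DIDataset, seed=None):
    """Stimulus-stratified 50/50 split of kept rows, per trial.

    Within every trial the kept rows are randomly partitioned in half
    (trials belong to single stimuli, so the split is stratified by
    stimulus by construction).  A trial with a single row goes to train
    with a warning.  Returns (train, test) datasets.
    """
    rng = np.random.default_rng(seed)
    train_rows, test_rows = [], []
    for tr in np.unique(dataset.trial_index):
        rows = np.flatnonzero(dataset.trial_index == tr)
        if rows.size == 1:
            warnings.warn(f"trial {tr} has a single kept row; assigned to train")
            train_rows.append(rows)
            continue
        perm = rng.permutation(rows)
        half = rows.size // 2
        train_rows.append(np.sort(perm[: rows.size - half]))
        test_rows.append(np.sort(perm[rows.size - half:]))
    train_idx = np.concatenate(train_rows) if train_rows else np.empty(0, int)
    test_idx = np.concatenate(test_rows) if test_rows else np.empty(0, int)
    return dataset.take(np.sort(train_idx)), dataset.take(np.sort(test_idx))


@dataclass
class DIModel:
    """Fitted lasso-logistic model for one candidate set."""

    coef: np.ndarray
    intercept: float
    lambda_: float
    candidates: list
    tag: str = ""
    cv_nll: np.ndarray = None  # mean held-fold NLL per lambda

    def predict_proba(self, X) -> np.ndarray:
        """P(Y(t) = 1 | features)."""
        z = np.asarray(X, dtype=float) @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def _fit_at_lambda(X, y, lam):
    # lasso objective sum_t NLL + lambda * |theta|_1  <=>  sklearn
    # |theta|_1 + C * sum NLL with C = 1 / lambda
    C = 1.0 / lam
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=1e-6, max_iter=1000,
        random_state=0,
    )
    clf.fit(X, y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def _nll(y, p):
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_lasso_logistic_cv(
    train: DIDataset,
    candidate_subset=None,
    lambda_grid=LAMBDA_GRID,
    folds: int = 5,
    seed=None,
    tag: str = "",
) -> DIModel:
    """5-fold CV over the lasso penalty grid, then refit on all train rows.

    The selection criterion is the mean held-fold empirical negative log
    likelihood; the winning penalty's model is refit on the full training
    set.  Deterministic for a fixed seed.
    """
    cands = list(train.candidates) if candidate_subset is None else list(candidate_subset)
    X = train.columns_for(cands).astype(float)
    y = train.y.astype(int)
    if np.unique(y).size < 2:
        raise DegenerateModelError(
            f"target {train.target!r}: single-class training data"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(y.size)
    fold_of = np.empty(y.size, dtype=int)
    fold_of[order] = np.arange(y.size) % folds

    lambda_grid = np.asarray(lambda_grid, dtype=float)
    mean_nll = np.full(lambda_grid.size, np.inf)
    for li, lam in enumerate(lambda_grid):
        nlls = []
        for k in range(folds):
            tr_m = fold_of != k
            if np.unique(y[tr_m]).size < 2 or (~tr_m).sum() == 0:
                continue
            coef, b = _fit_at_lambda(X[tr_m], y[tr_m], lam)
            p = 1.0 / (1.0 + np.exp(-(X[~tr_m] @ coef + b)))
            nlls.append(_nll(y[~tr_m], p))
        if nlls:
            mean_nll[li] = float(np.mean(nlls))
    best = int(np.argmin(mean_nll))
    coef, b = _fit_at_lambda(X, y, lambda_grid[best])
    return DIModel(coef, b, float(lambda_grid[best]), cands, tag, mean_nll)


def directed_information(test: DIDataset, full: DIModel, reduced: DIModel) -> float:
    """Normalized held-out directed information of full vs reduced model.

    (1/T) sum_t log2 [P_full / P_reduced] over the test rows, divided by
    the empirical binary entropy of Y on those rows.  May legitimately be
    negative on held-out data; values are reported unclipped.
    """
    if not set(reduced.candidates) <= set(full.candidates):
        raise ValueError("reduced model's candidates must be a subset of the full model's")
    y = test.y.astype(float)
    T = y.size
    if T == 0:
        raise ValueError("empty test set")
    p_hat = float(y.mean())
    if p_hat in (0.0, 1.0):
        raise DegenerateModelError(f"target {test.target!r}: constant Y on test rows")
    h = -(p_hat * np.log2(p_hat) + (1 - p_hat) * np.log2(1 - p_hat))
    eps = 1e-12
    p_full = np.clip(full.predict_proba(test.columns_for(full.candidates)), eps, 1 - eps)
    p_red = np.clip(
        reduced.predict_proba(test.columns_for(reduced.candidates)), eps, 1 - eps
    )
    ll_full = np.where(y == 1, np.log2(p_full), np.log2(1 - p_full))
    ll_red = np.where(y == 1, np.log2(p_red), np.log2(1 - p_red))
    return float(np.mean(ll_full - ll_red) / h)


def shapley_attribution(i_all, i_v1, i_hva, i_none=0.0):
    """Two-player Shapley split of the total directed information.

    Averages each area's marginal contribution over the two inclusion
    orders; the shares sum to i_all - i_none exactly.
    """
    shap_v1 = 0.5 * (i_all - i_hva) + 0.5 * (i_v1 - i_none)
    shap_hva = 0.5 * (i_all - i_v1) + 0.5 * (i_hva - i_none)
    return shap_v1, shap_hva


@dataclass
class DIResult:
    """Normalized DI values and Shapley attributions for one target unit."""

    target: object
    target_area: str
    i_all: float
    i_area1: float
    i_area2: float
    i_none: float
    shap_area1: float
    shap_area2: float
    n_test: int
    per_stimulus: dict = field(default_factory=dict)
    # per stimulus id: dict with i_all, i_area1, i_area2, shap_area1, shap_area2


def evaluate_target(
    session: Session,
    target,
    area1: str,
    area2: str,
    seed=None,
    lambda_grid=LAMBDA_GRID,
    per_stimulus: bool = True,
) -> DIResult:
    """Fit the four candidate-set models for one target and evaluate DI.

    Candidate sets: all simultaneously recorded units except the target,
    area-1 units only, area-2 units only, and none (self-history only,
    the reduced model for every evaluation, hence I_None = 0).  The
    imbalance mask is built once against the full candidate set so all
    four models score identical rows.  DI is evaluated on all test rows
    and, per SF/TF stimulus, on that stimulus's test rows.

    Raises :class:`DegenerateModelError` when the target's rows are
    single-class; callers exclude such units.
    """
    cand1 = [u for u in session.units_of_area(area1) if u != target]
    cand2 = [u for u in session.units_of_area(area2) if u != target]
    cands = cand1 + cand2
    if not cands:
        raise ValueError("no candidate units besides the target")
    ds = build_dataset(session, target, cands)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    s_split, s_all, s_a1, s_a2, s_none = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    ]
    train, test = split_train_test(ds, seed=s_split)
    m_all = fit_lasso_logistic_cv(train, cands, lambda_grid, seed=s_all, tag="All")
    m_a1 = fit_lasso_logistic_cv(train, cand1, lambda_grid, seed=s_a1, tag=area1) \
        if cand1 else None
    m_a2 = fit_lasso_logistic_cv(train, cand2, lambda_grid, seed=s_a2, tag=area2) \
        if cand2 else None
    m_none = fit_lasso_logistic_cv(train, [], lambda_grid, seed=s_none, tag="None")

    def _eval(sub: DIDataset):
        i_all = directed_information(sub, m_all, m_none)
        i_1 = directed_information(sub, m_a1, m_none) if m_a1 else 0.0
        i_2 = directed_information(sub, m_a2, m_none) if m_a2 else 0.0
        i_none = directed_information(sub, m_none, m_none)  # exactly 0
        s1, s2 = shapley_attribution(i_all, i_1, i_2, i_none)
        return dict(i_all=i_all, i_area1=i_1, i_area2=i_2, i_none=i_none,
                    shap_area1=s1, shap_area2=s2)

    overall = _eval(test)
    per_stim = {}
    if per_stimulus:
        for sid in np.unique(test.stimulus_id):
            sub = test.take(np.flatnonzero(test.stimulus_id == sid))
            try:
                per_stim[int(sid)] = _eval(sub)
            except (DegenerateModelError, ValueError):
                continue
    area_t = str(session.units.loc[target, "area"])
    return DIResult(
        target, area_t, overall["i_all"], overall["i_area1"], overall["i_area2"],
        overall["i_none"], overall["shap_area1"], overall["shap_area2"],
        test.n_rows, per_stim,
    )


# ---------------------------------------------------------------------------
# area-level connectivity grids
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityGrid:
    """5 x 5 SF/TF connectivity summary for one ordered area pair."""

    source: str
    dest: str
    median_pre: np.ndarray    # (5, 5), NaN where missing
    median_post: np.ndarray
    diff: np.ndarray          # post - pre
    pvalues: np.ndarray
    reject: np.ndarray        # BH-FDR decisions at alpha
    n_pre: np.ndarray
    n_post: np.ndarray
    alpha: float


def connectivity_grid_from_weights(
    weights_pre: dict,
    weights_post: dict,
    source: str,
    dest: str,
    n_perm: int = 10_000,
    seed=None,
    alpha: float = 0.05,
    grid: StimulusGrid = None,
) -> ConnectivityGrid:
    """Median-difference grid with per-cell permutation p and BH-FDR.

    ``weights_pre``/``weights_post`` map flat stimulus ids to arrays of
    per-target-unit attributed normalized DI (or any edge weight, e.g.
    PLV or PPC).  Each cell's two-sided permutation test relabels the
    pooled weights preserving the pre/post proportions; FDR correction
    runs across the grid's cells (one area pair at a time).
    """
    grid = grid or StimulusGrid()
    shape = (len(grid.sfs), len(grid.tfs))
    med_pre = np.full(shape, np.nan)
    med_post = np.full(shape, np.nan)
    pmat = np.full(shape, np.nan)
    n_pre = np.zeros(shape, dtype=int)
    n_post = np.zeros(shape, dtype=int)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    cell_seeds = {
        sid: int(s.generate_state(1)[0] % (2**31))
        for sid, s in zip(range(grid.n_stimuli), ss.spawn(grid.n_stimuli))
    }
    flat_p, cells = [], []
    for sid in range(grid.n_stimuli):
        i, j = grid.indices(sid)
        a = np.asarray(weights_post.get(sid, []), dtype=float)
        b = np.asarray(weights_pre.get(sid, []), dtype=float)
        n_post[i, j], n_pre[i, j] = a.size, b.size
        if a.size == 0 or b.size == 0:
            continue
        med_post[i, j], med_pre[i, j] = np.median(a), np.median(b)
        res = perm_test_median_diff(a, b, n_iter=n_perm, seed=cell_seeds[sid])
        pmat[i, j] = res.pvalue
        flat_p.append(res.pvalue)
        cells.append((i, j))
    reject = np.zeros(shape, dtype=bool)
    if flat_p:
        rej, _ = fdr_bh(flat_p, alpha=alpha)
        for (i, j), r in zip(cells, rej):
            reject[i, j] = bool(r)
    return ConnectivityGrid(
        source, dest, med_pre, med_post, med_post - med_pre, pmat, reject,
        n_pre, n_post, alpha,
    )


def area_connectivity(
    sessions,
    condition_pair: tuple = ("pre", "postA"),
    n_perm: int = 10_000,
    seed=None,
    alpha: float = 0.05,
    lambda_grid=LAMBDA_GRID,
):
    """Full area-level connectivity change analysis over a session set.

    For every target unit in every session, fits the four candidate-set
    models and attributes per-stimulus normalized DI to the two source
    areas; pools attributed weights per (ordered area pair, stimulus,
    condition); and returns one :class:`ConnectivityGrid` per ordered
    area pair with post-minus-pre median differences, per-cell
    permutation p values, and BH-FDR decisions (corrected separately per
    area pair).  Deterministic given the seed.
    """
    sessions = list(sessions)
    areas = sorted({a for s in sessions for a in dict.fromkeys(s.channel_areas)})
    if len(areas) != 2:
        raise ValueError(f"expected exactly two areas across sessions, got {areas}")
    a1, a2 = areas
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    sess_seeds = iter(ss.spawn(len(sessions) * 64))
    # weights[(src, dst)][condition][sid] -> list of per-target weights
    weights = {
        pair: {c: {} for c in condition_pair}
        for pair in ((a1, a2), (a2, a1))
    }
    for sess in sessions:
        cond = str(sess.trials["condition"].iloc[0])
        if cond not in condition_pair:
            continue
        for target in sess.units.index:
            s = int(next(sess_seeds).generate_state(1)[0] % (2**31))
            try:
                res = evaluate_target(sess, target, a1, a2, seed=s,
                                      lambda_grid=lambda_grid)
            except DegenerateModelError:
                continue
            dst = res.target_area
            for sid, vals in res.per_stimulus.items():
                for src, key in ((a1, "shap_area1"), (a2, "shap_area2")):
                    if src == dst:
                        continue
                    weights[(src, dst)][cond].setdefault(sid, []).append(vals[key])
    grids = {}
    pre_tag, post_tag = condition_pair
    for k, pair in enumerate(((a1, a2), (a2, a1))):
        grids[pair] = connectivity_grid_from_weights(
            weights[pair][pre_tag], weights[pair][post_tag], pair[0], pair[1],
            n_perm=n_perm, seed=(0 if seed is None else seed) + 7919 * (k + 1),
            alpha=alpha,
        )
    return grids
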