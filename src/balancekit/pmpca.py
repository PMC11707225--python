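"""Waveform PCA of joint-angle time series and group comparison on scores.

The procedure condenses each participant's 10-s, 12-channel joint-angle
record (1,000 time points x 12 channels = 12,000 variables at 100 Hz) into
a small set of principal movement patterns:

1. average the three trials per participant pointwise;
2. z-score every variable across participants, Z_t = (X_t - mu_t)/s_t;
3. stack participants into an n x 12,000 matrix;
4. extract principal components until 90% of total variance is described;
5. compare the groups by independent t-tests on each retained component's
   scores (PCSs), with Cohen's d;
6. reconstruct interpretable group-mean waveforms from mean scores through
   the loadings (PCVs) and the inverse z-transform.

Stability of a score-level group difference is checked by leave-one-out
surrogate PCAs: the fit is repeated n times with one participant left out,
the surrogate component best matching the target loading pattern is
identified, and the group test re-run.

Standardization is column-wise across participants (the only reading under
which the per-variable SD is defined for a scalar per participant); sample
(n-1) SDs throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinem import JOINTS, PLANES, JointAngleTensor

logger = logging.getLogger(__name__)

_SD_FLOOR = 1e-12


class AssemblyError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# step 1: intra-participant averaging
# ---------------------------------------------------------------------------

def intra_participant_average(trials) -> JointAngleTensor:
    """Pointwise mean of a participant's trial tensors (same channels/length)."""
    trials = list(trials)
    if not trials:
        raise AssemblyError("no trials to average")
    n = trials[0].n_samples
    rate = trials[0].rate
    for t in trials[1:]:
        if t.n_samples != n:
            raise AssemblyError(
                f"trial length mismatch: {t.n_samples} vs {n}")
        if t.rate != rate:
            raise AssemblyError("trial sampling-rate mismatch")
    return JointAngleTensor(
        np.mean([t.angles for t in trials], axis=0), rate)


# ---------------------------------------------------------------------------
# steps 2-3: assembly and standardization
# ---------------------------------------------------------------------------

@dataclass
class ZScoreParams:
    """Column-wise standardization parameters over the variable axis.

    ``mu``/``sd`` have one entry per original variable (channel-major then
    time layout, see :meth:`JointAngleTensor.flat`); ``kept`` marks columns
    with sd above the degeneracy floor — only those enter the PCA.
    """

    mu: np.ndarray
    sd: np.ndarray
    kept: np.ndarray

    @property
    def n_variables(self) -> int:
        return self.mu.size

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return (X[:, self.kept] - self.mu[self.kept]) / self.sd[self.kept]

    def inverse(self, Z_kept: np.ndarray) -> np.ndarray:
        """Back to original units; dropped columns take their mean value."""
        Z_kept = np.atleast_2d(Z_kept)
        out = np.tile(self.mu, (Z_kept.shape[0], 1))
        out[:, self.kept] = self.mu[self.kept] + self.sd[self.kept] * Z_kept
        return out


def waveform_matrix(averages) -> np.ndarray:
    """Stack participant average tensors into (n_participants, n_variables)."""
    rows = [t.flat() if isinstance(t, JointAngleTensor) else np.asarray(t, float)
            for t in averages]
    p = rows[0].size
    for r in rows[1:]:
        if r.size != p:
            raise AssemblyError("participants contribute unequal variable counts")
    return np.vstack(rows)


def assemble_and_standardize(averages):
    """Build the z-scored participants-by-variables matrix.

    ``averages`` is an ordered iterable of participant average tensors (or
    flat rows). Returns ``(Z, params)`` with ``Z`` restricted to columns of
    non-degenerate variance; dropped columns are reported through the module
    logger.
    """
    X = waveform_matrix(averages)
    if X.shape[0] < 2:
        raise AssemblyError("need at least 2 participants to standardize")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    kept = sd > _SD_FLOOR
    dropped = int((~kept).sum())
    if dropped:
        logger.warning("dropping %d constant variables before PCA", dropped)
    params = ZScoreParams(mu=mu, sd=sd, kept=kept)
    Z = (X[:, kept] - mu[kept]) / sd[kept]
    return Z, params


# ---------------------------------------------------------------------------
# step 4: PCA with 90% retention
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """SVD-based principal components of the standardized waveform matrix.

    ``loadings`` (n_components x n_kept_variables, orthonormal rows) and
    ``scores`` (n_participants x n_components) cover the full basis;
    ``retained_k`` components reach the variance threshold.
    ``sign_flips`` records the orientation applied per component.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    retained_k: int
    variance_threshold: float
    sign_flips: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def reconstruct_standardized(self, scores: np.ndarray,
                                 components=None) -> np.ndarray:
        """Z-space reconstruction from score vectors through the loadings."""
        comps = np.arange(self.retained_k) if components is None else \
            np.asarray(components, dtype=int)
        if comps.size and comps.max() >= self.n_components:
            raise IndexError(f"component index {comps.max()} out of range")
        S = np.atleast_2d(scores)
        return S[:, comps] @ self.loadings[comps]


def fit_pca(Z: np.ndarray, variance_threshold: float = 0.90,
            groups=None, positive_group: str = "HC") -> PCAResult:
    """Principal components of the participant-centred matrix via SVD.

    Retains the minimal number of components whose cumulative explained
    variance reaches ``variance_threshold``. When ``groups`` is given, each
    component's sign is oriented so the ``positive_group`` mean score is
    non-negative; otherwise the largest-|loading| element is made positive.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n < 3:
        raise InsufficientDataError("need at least 3 participants for PCA")
    Zc = Z - Z.mean(axis=0)
    U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    # drop numerically null directions introduced by centring
    keep = S > S[0] * 1e-12 if S[0] > 0 else S > -1.0
    U, S, Vt = U[:, keep], S[keep], Vt[keep]
    evr = S**2 / np.sum(S**2)
    cum = np.cumsum(evr)
    retained_k = int(np.searchsorted(cum, variance_threshold) + 1)
    retained_k = min(retained_k, S.size)
    scores = U * S
    flips = np.ones(S.size)
    if groups is not None:
        groups = np.asarray(groups)
        mask = groups == positive_group
        if not mask.any():
            raise ValueError(f"no participants in group {positive_group!r}")
        mean_scores = scores[mask].mean(axis=0)
        flips = np.where(mean_scores < 0, -1.0, 1.0)
    else:
        peak = np.argmax(np.abs(Vt), axis=1)
        flips = np.sign(Vt[np.arange(Vt.shape[0]), peak])
        flips[flips == 0] = 1.0
    return PCAResult(
        loadings=Vt * flips[:, None],
        scores=scores * flips[None, :],
        explained_variance_ratio=evr,
        retained_k=retained_k,
        variance_threshold=variance_threshold,
        sign_flips=flips,
    )


# ---------------------------------------------------------------------------
# step 5: group tests on scores
# ---------------------------------------------------------------------------

def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                 / (na + nb - 2))
    if sp == 0:
        return 0.0 if a.mean() == b.mean() else np.inf
    return float((b.mean() - a.mean()) / sp)


def test_group_scores(result: PCAResult, groups, components=None,
                      equal_var: bool = True,
                      group_order: tuple = ("HC", "CAI")) -> pd.DataFrame:
    """Independent t-tests on the scores of each (retained) component.

    Returns one row per component with t, p, Cohen's d and group mean
    scores. d is the second group of ``group_order`` relative to the first
    (default CAI - HC, matching negative d when CAI scores sit below HC).
    No multiple-testing correction is applied; ``n_tests`` reports the
    family size so readers can judge the uncorrected inference.
    """
    groups = np.asarray(groups)
    ref, other = group_order
    a = result.scores[groups == ref]
    b = result.scores[groups == other]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InsufficientDataError("each group needs at least 2 members")
    comps = np.arange(result.retained_k) if components is None else \
        np.asarray(components, dtype=int)
    rows = []
    for c in comps:
        t, p = stats.ttest_ind(b[:, c], a[:, c], equal_var=equal_var)
        rows.append(dict(
            component=int(c) + 1,
            t=float(t), p=float(p),
            cohens_d=_cohens_d(a[:, c], b[:, c]),
            mean_score_ref=float(a[:, c].mean()),
            mean_score_other=float(b[:, c].mean()),
            n_tests=comps.size,
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# step 6: waveform reconstruction
# ---------------------------------------------------------------------------

def reconstruct_group_waveforms(result: PCAResult, params: ZScoreParams,
                                mean_scores: dict, components,
                                n_channels: int = len(JOINTS) * len(PLANES)):
    """Group-mean joint-angle waveforms from mean scores, original units.

    ``mean_scores`` maps a label (group name, 'ALL', or a participant id)
    to a full score vector or retained-length vector; ``components``
    selects which loadings carry the reconstruction. Returns
    {label: (12, n_time) degrees}.
    """
    comps = np.asarray(components, dtype=int)
    out = {}
    for label, sc in mean_scores.items():
        sc = np.asarray(sc, dtype=float)
        full = np.zeros(result.n_components)
        full[: sc.size] = sc
        z = result.reconstruct_standardized(full, comps)
        x = params.inverse(z)[0]
        out[label] = x.reshape(n_channels, -1)
    return out


def group_mean_scores(result: PCAResult, groups) -> dict:
    groups = np.asarray(groups)
    out = {g: result.scores[groups == g].mean(axis=0) for g in np.unique(groups)}
    out["ALL"] = result.scores.mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# leave-one-out surrogate validation
# ---------------------------------------------------------------------------

def match_component(target_loading: np.ndarray, loadings: np.ndarray,
                    ambiguity_margin: float = 0.01):
    """Best surrogate component by absolute loading correlation.

    Returns ``(index, signed_r, ambiguous)`` where ``ambiguous`` flags a
    runner-up within ``ambiguity_margin`` of the winner in |r|.
    """
    t = target_loading - target_loading.mean()
    L = loadings - loadings.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(t) * np.linalg.norm(L, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (L @ t) / denom
    r = np.nan_to_num(r)
    order = np.argsort(-np.abs(r))
    best = int(order[0])
    ambiguous = order.size > 1 and (
        np.abs(r[best]) - np.abs(r[order[1]]) < ambiguity_margin)
    return best, float(r[best]), ambiguous


def loo_surrogate_validation(averages, groups, target_component: int,
                             variance_threshold: float = 0.90,
                             participant_ids=None,
                             alpha: float = 0.05,
                             marginal: float = 0.10) -> pd.DataFrame:
    """Leave-one-out surrogate PCAs testing stability of a group difference.

    For each of the n participants the PCA is refit on the other n-1 rows
    (re-standardized from raw averages), the surrogate component best
    matching the full-fit ``target_component`` loading (0-based, within the
    retained set) is found by maximal |loading correlation| with sign
    alignment, and the group t-test on its scores is re-run. Rows classify
    each surrogate as significant (p < alpha), marginal (alpha <= p <
    ``marginal``) or ns.
    """
    X = waveform_matrix(averages)
    groups = np.asarray(groups)
    n = X.shape[0]
    if n < 4:
        raise InsufficientDataError("need at least 4 participants for LOO")
    if participant_ids is None:
        participant_ids = [f"P{i+1:02d}" for i in range(n)]
    Z_full, params_full = assemble_and_standardize(X)
    full = fit_pca(Z_full, variance_threshold, groups=groups)
    if not (0 <= target_component < full.retained_k):
        raise IndexError(
            f"target component {target_component} outside retained set "
            f"(k={full.retained_k})")
    target_kept = params_full.kept
    target = full.loadings[target_component]

    rows = []
    for i in range(n):
        keep_rows = np.arange(n) != i
        Z_i, params_i = assemble_and_standardize(X[keep_rows])
        fit_i = fit_pca(Z_i, variance_threshold, groups=groups[keep_rows])
        common = target_kept & params_i.kept
        t_common = np.zeros(params_full.n_variables)
        t_common[target_kept] = target
        l_full = np.zeros((fit_i.n_components, params_i.n_variables))
        l_full[:, params_i.kept] = fit_i.loadings
        idx, r, ambiguous = match_component(
            t_common[common], l_full[:, common])
        sign = 1.0 if r >= 0 else -1.0
        sc = fit_i.scores[:, idx] * sign
        g = groups[keep_rows]
        a, b = sc[g == "HC"], sc[g == "CAI"]
        t_stat, p = stats.ttest_ind(b, a, equal_var=True)
        cls = ("significant" if p < alpha
               else "marginal" if p < marginal else "ns")
        rows.append(dict(
            left_out=participant_ids[i],
            matched_component=int(idx) + 1,
            match_r=abs(r),
            ambiguous=bool(ambiguous),
            matrix_rows=int(keep_rows.sum()),
            matrix_cols=int(params_i.kept.sum()),
            t=float(t_stat), p=float(p),
            cohens_d=_cohens_d(a, b),
            classification=cls,
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# score-balance correlations
# ---------------------------------------------------------------------------

def correlate_scores_with_balance(scores, metric, groups=None) -> pd.DataFrame:
    """Pearson correlation of a component's scores with a balance metric.

    One row overall plus one per group when ``groups`` is supplied.
    """
    scores = np.asarray(scores, dtype=float)
    metric = np.asarray(metric, dtype=float)
    if scores.size != metric.size:
        raise ValueError("scores and metric must be paired")
    if scores.size < 3:
        raise InsufficientDataError("need at least 3 participants")
    if np.isnan(scores).any() or np.isnan(metric).any():
        raise ValueError("missing values are not allowed")

    def one(label, s, m):
        if np.std(s) == 0 or np.std(m) == 0:
            raise UndefinedCorrelationError(
                f"zero variance in {label!r} correlation inputs")
        r, p = stats.pearsonr(s, m)
        return dict(subset=label, n=s.size, r=float(r), p=float(p))

    rows = [one("ALL", scores, metric)]
    if groups is not None:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            mask = groups == g
            rows.append(one(str(g), scores[mask], metric[mask]))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def loadings_frame(result: PCAResult, components=None) -> pd.DataFrame:
    comps = np.arange(result.retained_k) if components is None else components
    rows = []
    for c in comps:
        for vi, val in enumerate(result.loadings[c]):
            rows.append(dict(component=int(c) + 1, variable_index=vi,
                             loading=float(val)))
    return pd.DataFrame(rows)


def scores_frame(result: PCAResult, participant_ids) -> pd.DataFrame:
    rows = []
    for pi, pid in enumerate(participant_ids):
        for c in range(result.retained_k):
            rows.append(dict(participant=pid, component=c + 1,
                             score=float(result.scores[pi, c])))
    return pd.DataFrame(rows)
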