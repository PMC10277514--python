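"""Fixed-specificity biomarker panels.

Per-protein empirical ROC analysis, thresholding at a target specificity,
k-of-n combination of single-marker tests (classify positive when at least k
of n thresholded tests are positive), McNemar comparison of paired rules,
and marker-subset selection by exhaustive information-criterion search over
maximum-likelihood logistic fits.

Operating points are resubstitution (derivation-set) estimates by default —
the honest-but-optimistic convention the panel derivation calls for; a
cross-validated evaluation can be layered on by the caller.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import NPXMatrix
from .stats import TestResult, mcnemar

__all__ = [
    "ThresholdedTest",
    "PanelRule",
    "roc_curve",
    "roc_auc",
    "threshold_at_specificity",
    "derive_test",
    "evaluate_k_of_n",
    "compare_panels_mcnemar",
    "select_subset_logistic",
]


@dataclass(frozen=True)
class ThresholdedTest:
    """A single-protein decision rule at a fixed threshold."""

    protein: str
    direction: str                 # "greater" -> above threshold is positive
    threshold: float
    specificity: float             # achieved on the derivation set
    sensitivity: float

    def __post_init__(self):
        if self.direction not in ("greater", "less"):
            raise ValueError(f"direction must be greater|less, got {self.direction!r}")

    def decide(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        if self.direction == "greater":
            return s > self.threshold
        return s < self.threshold


@dataclass
class PanelRule:
    """k-of-n combination of thresholded tests with its operating points."""

    tests: list[ThresholdedTest]
    operating_points: pd.DataFrame = field(repr=False)  # k, sensitivity, specificity
    positives_per_sample: pd.Series = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.tests)

    def decide(self, k: int) -> pd.Series:
        if not (0 <= k <= self.n):
            raise ValueError(f"k={k} outside [0, {self.n}]")
        return self.positives_per_sample >= k

    def operating_point(self, k: int) -> tuple[float, float]:
        row = self.operating_points.loc[self.operating_points["k"] == k]
        return float(row["sensitivity"].iloc[0]), float(row["specificity"].iloc[0])


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("ROC requires both cases and controls")
    return y


def roc_curve(scores, labels, direction: str = "greater") -> pd.DataFrame:
    """Empirical ROC over all distinct thresholds.

    Positive means score strictly beyond the threshold (above for
    ``greater``, below for ``less``), so each observed value is itself a
    usable cut.  Returns a frame with columns threshold, sensitivity,
    specificity, ordered from the all-positive to the all-negative rule.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_labels(labels)
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    uniq = np.unique(s)
    if direction == "greater":
        thresholds = np.concatenate([[-np.inf], uniq])
    else:
        thresholds = np.concatenate([[np.inf], uniq[::-1]])
    rows = []
    n_case, n_ctrl = int(y.sum()), int((~y).sum())
    for thr in thresholds:
        pos = s > thr if direction == "greater" else s < thr
        rows.append(
            dict(
                threshold=float(thr),
                sensitivity=float((pos & y).sum() / n_case),
                specificity=float((~pos & ~y).sum() / n_ctrl),
            )
        )
    return pd.DataFrame(rows)


def roc_auc(roc: pd.DataFrame) -> float:
    """Area under the empirical ROC by the trapezoid rule."""
    fpr = (1.0 - roc["specificity"]).to_numpy()
    tpr = roc["sensitivity"].to_numpy()
    order = np.lexsort((tpr, fpr))    # staircase corners in traversal order
    return float(np.trapezoid(tpr[order], fpr[order]))


def threshold_at_specificity(
    roc: pd.DataFrame, target: float, protein: str = "", direction: str = "greater"
) -> ThresholdedTest:
    """The operating point with the smallest achieved specificity >= target.

    A tie on specificity is broken toward larger sensitivity.  Always
    attainable: the all-negative rule has specificity 1.
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target specificity must lie in (0, 1)")
    ok = roc[roc["specificity"] >= target]
    if ok.empty:
        raise ValueError("no threshold achieves the target specificity")
    best = ok.sort_values(
        ["specificity", "sensitivity"], ascending=[True, False], kind="stable"
    ).iloc[0]
    return ThresholdedTest(
        protein=protein,
        direction=direction,
        threshold=float(best["threshold"]),
        specificity=float(best["specificity"]),
        sensitivity=float(best["sensitivity"]),
    )


def derive_test(
    matrix: NPXMatrix, labels: pd.Series, protein: str,
    direction: str, target_specificity: float,
) -> ThresholdedTest:
    """ROC + fixed-specificity thresholding for one protein."""
    if protein not in matrix.values.columns:
        raise KeyError(f"protein {protein!r} not in matrix")
    scores = matrix.values[protein].loc[labels.index]
    roc = roc_curve(scores.to_numpy(), labels.to_numpy(), direction)
    return threshold_at_specificity(roc, target_specificity, protein, direction)


# ---------------------------------------------------------------------------
# k-of-n combination
# ---------------------------------------------------------------------------

def evaluate_k_of_n(
    tests: list[ThresholdedTest], matrix: NPXMatrix, labels: pd.Series
) -> PanelRule:
    """Count per-sample positive tests and emit the full k = 0..n continuum.

    Sensitivity is non-increasing and specificity non-decreasing in k by
    construction (the positive sets are nested); this is asserted, not
    assumed.
    """
    missing = [t.protein for t in tests if t.protein not in matrix.values.columns]
    if missing:
        raise KeyError(f"panel proteins missing from matrix: {missing}")
    y = _check_labels(labels.to_numpy())
    sub = matrix.values.loc[labels.index]
    pos_counts = pd.Series(0, index=labels.index, dtype=int)
    for t in tests:
        pos_counts += t.decide(sub[t.protein].to_numpy()).astype(int)

    n_case, n_ctrl = int(y.sum()), int((~y).sum())
    rows = []
    for k in range(len(tests) + 1):
        pos = (pos_counts >= k).to_numpy()
        rows.append(
            dict(
                k=k,
                sensitivity=float((pos & y).sum() / n_case),
                specificity=float((~pos & ~y).sum() / n_ctrl),
            )
        )
    points = pd.DataFrame(rows)
    sens = points["sensitivity"].to_numpy()
    spec = points["specificity"].to_numpy()
    if np.any(np.diff(sens) > 1e-12) or np.any(np.diff(spec) < -1e-12):
        raise AssertionError("k-of-n operating points violate monotonicity")
    return PanelRule(list(tests), points, pos_counts)


def compare_panels_mcnemar(
    decisions_a: pd.Series,
    decisions_b: pd.Series,
    labels: pd.Series,
    among: str = "cases",
    mode: str = "exact",
) -> TestResult:
    """McNemar on discordant classifications of two rules on paired samples.

    ``among="cases"`` compares sensitivities (a correct call is a positive);
    ``among="controls"`` compares specificities (a correct call is a
    negative).  The returned note states which comparison was made and the
    discordant counts.
    """
    if not decisions_a.index.equals(decisions_b.index) or not decisions_a.index.equals(
        labels.index
    ):
        raise ValueError("decision vectors and labels must be paired on the same samples")
    y = labels.astype(bool)
    if among == "cases":
        sel = y
        correct_a = decisions_a[sel].astype(bool)
        correct_b = decisions_b[sel].astype(bool)
    elif among == "controls":
        sel = ~y
        correct_a = ~decisions_a[sel].astype(bool)
        correct_b = ~decisions_b[sel].astype(bool)
    else:
        raise ValueError("among must be 'cases' or 'controls'")
    b = int((correct_a & ~correct_b).sum())
    c = int((~correct_a & correct_b).sum())
    res = mcnemar(b, c, mode=mode)
    return TestResult(
        res.statistic, res.p_value, "mcnemar", exact=res.exact,
        note=f"{'sensitivity' if among == 'cases' else 'specificity'} "
             f"comparison; discordant b={b}, c={c}",
    )


# ---------------------------------------------------------------------------
# logistic subset selection
# ---------------------------------------------------------------------------

def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    """Newton/IRLS fit; returns (beta, unpenalized loglik, separated flag)."""
    n, p = X.shape
    beta = np.zeros(p)
    separated = False
    eye = np.eye(p)
    for _ in range(40):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + (ridge + 1e-12) * eye
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # dampen huge steps for stability
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if np.max(np.abs(beta)) > 25.0:
            separated = True   # coefficients diverging: (quasi-)separation
            break
        if norm < 1e-8:
            break
    if np.max(np.abs(beta)) > 25.0:
        separated = True
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    ll = float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))
    return beta, ll, separated


def _fit_logistic_batch(X3: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    """Newton/IRLS on a (B, n, p) stack of design matrices at once.

    Same update as _fit_logistic but vectorized across B candidate subsets;
    returns (beta (B,p), unpenalized loglik (B,), separated flag (B,)).
    """
    B, n, p = X3.shape
    beta = np.zeros((B, p))
    active = np.ones(B, dtype=bool)
    separated = np.zeros(B, dtype=bool)
    eye = np.eye(p)
    for _ in range(40):
        idx = np.where(active)[0]
        if idx.size == 0:
            break
        Xa = X3[idx]
        ba = beta[idx]
        eta = np.clip(np.einsum("bnp,bp->bn", Xa, ba), -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = np.einsum("bnp,bn->bp", Xa, y - mu) - ridge * ba
        H = np.einsum("bnp,bn,bnq->bpq", Xa, w, Xa) + (ridge + 1e-12) * eye
        try:
            step = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(H[i], grad[i], rcond=None)[0] for i in range(len(idx))]
            )
        norm = np.max(np.abs(step), axis=1)
        big = norm > 10.0
        if big.any():
            step[big] *= (10.0 / norm[big])[:, None]
        ba = ba + step
        beta[idx] = ba
        div = np.max(np.abs(ba), axis=1) > 25.0
        separated[idx[div]] = True
        active[idx[(norm < 1e-8) | div]] = False
    eta = np.clip(np.einsum("bnp,bp->bn", X3, beta), -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    ll = np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps), axis=1)
    return beta, ll, separated


def _criterion(ll: float, k_params: int, n: int, which: str) -> float:
    if which == "aic":
        return 2.0 * k_params - 2.0 * ll
    if which == "bic":
        return float(np.log(n)) * k_params - 2.0 * ll
    raise ValueError(f"unknown criterion {which!r}")


def select_subset_logistic(
    matrix: NPXMatrix,
    labels: pd.Series,
    candidates: list[str],
    max_size: int = 6,
    criterion: str = "aic",
):
    """Best marker subset by information criterion over logistic fits.

    Exhaustive search over all candidate subsets of size <= max_size when
    there are at most 20 candidates, greedy forward selection otherwise.
    Ties break to the lexicographically earliest subset (candidates are
    sorted by protein id first).  Perfect separation is flagged and the fit
    switched to a ridge-penalized likelihood.

    Returns (selected tuple of proteins, fitted probability Series, info dict).
    """
    y = labels.astype(bool).to_numpy().astype(float)
    if y.sum() < 10 or (1 - y).sum() < 10:
        raise ValueError("subset selection requires >= 10 samples per class")
    missing = [c for c in candidates if c not in matrix.values.columns]
    if missing:
        raise KeyError(f"candidates missing from matrix: {missing}")
    cand = sorted(candidates)
    sub = matrix.values.loc[labels.index]
    cols = {c: sub[c].to_numpy() for c in cand}
    n = len(y)

    def fit_subset(names: tuple[str, ...]):
        X = np.column_stack([np.ones(n)] + [cols[c] for c in names])
        beta, ll, sep = _fit_logistic(X, y)
        if sep:
            beta, ll, _ = _fit_logistic(X, y, ridge=1.0)
        score = _criterion(ll, len(names) + 1, n, criterion)
        return score, beta, ll, sep

    evaluated: dict[tuple[str, ...], float] = {}
    best = None  # (score, names, beta, ll, sep)

    if len(cand) <= 20:
        col_arr = np.column_stack([cols[c] for c in cand]) if cand else np.empty((n, 0))
        ones = np.ones((n, 1))
        for size in range(max_size + 1):
            subsets = list(itertools.combinations(range(len(cand)), size))
            if not subsets:
                continue
            X3 = np.stack(
                [np.hstack([ones, col_arr[:, list(s)]]) for s in subsets]
            )
            betas, lls, seps = _fit_logistic_batch(X3, y)
            if seps.any():
                for i in np.where(seps)[0]:
                    betas[i], lls[i], _ = _fit_logistic(X3[i], y, ridge=1.0)
            scores = _criterion(lls, size + 1, n, criterion)
            for i, s in enumerate(subsets):
                names = tuple(cand[j] for j in s)
                evaluated[names] = float(scores[i])
                if best is None or scores[i] < best[0] - 1e-9:
                    best = (float(scores[i]), names, betas[i], float(lls[i]),
                            bool(seps[i]))
    else:
        current: tuple[str, ...] = ()
        score, beta, ll, sep = fit_subset(current)
        evaluated[current] = score
        best = (score, current, beta, ll, sep)
        improved = True
        while improved and len(current) < max_size:
            improved = False
            step_best = None
            for c in cand:
                if c in current:
                    continue
                names = tuple(sorted(current + (c,)))
                score, beta, ll, sep = fit_subset(names)
                evaluated[names] = score
                if step_best is None or score < step_best[0] - 1e-9:
                    step_best = (score, names, beta, ll, sep)
            if step_best is not None and step_best[0] < best[0] - 1e-9:
                best = step_best
                current = step_best[1]
                improved = True

    score, names, beta, ll, sep = best
    X = np.column_stack([np.ones(n)] + [cols[c] for c in names])
    eta = np.clip(X @ beta, -35, 35)
    probs = pd.Series(1.0 / (1.0 + np.exp(-eta)), index=labels.index)
    info = dict(
        criterion=criterion,
        score=score,
        log_likelihood=ll,
        separated=sep,
        coefficients=dict(zip(("intercept",) + names, beta.tolist())),
        n_evaluated=len(evaluated),
        evaluated_scores=evaluated,
    )
    return names, probs, info
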