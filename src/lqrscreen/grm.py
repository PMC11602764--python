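"""Samejima's graded response model: MML-EM estimation and EAP trait scoring.

The graded response model (GRM) describes ordered polytomous item responses
``x in {0, ..., K-1}`` through cumulative boundary curves

    P*_k(theta) = logistic(a * (theta - b_k)),       k = 1, ..., K-1,

with discrimination ``a > 0`` and strictly increasing thresholds ``b_k``.
Category probabilities are adjacent differences, ``P_k = P*_k - P*_{k+1}``
with ``P*_0 = 1`` and ``P*_K = 0``.

Items are estimated by marginal maximum likelihood: the latent trait is
integrated out over a standard-normal prior on a quadrature grid (E-step),
and each item's parameters are updated by maximising the expected
complete-data log-likelihood (M-step).  The prior anchors the trait scale,
so no post-hoc standardisation is applied.  Respondents are scored by the
expected a posteriori (EAP) mean and posterior SD on the same grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

__all__ = [
    "ItemParameters",
    "ResponseMatrix",
    "LatentTraitEstimate",
    "QuadratureConfig",
    "EstimationError",
    "category_probabilities",
    "expected_response",
    "estimate_theta_eap",
    "eap_scores",
    "save_item_bank",
    "load_item_bank",
    "GradedResponseModel",
    "GRMResults",
    "fit_grm",
]

_MISSING = -1  # internal sentinel for missing category codes


class EstimationError(RuntimeError):
    """Raised when the GRM cannot be estimated from the data provided."""


@dataclass(frozen=True)
class ItemParameters:
    """Discrimination and ordered category thresholds of one GRM item.

    Parameters
    ----------
    item_id : str
        Identifier used in response-matrix columns and feature names.
    discrimination : float
        Logistic slope ``a``; must be positive.
    thresholds : tuple of float
        Boundary locations ``b_1 < ... < b_{K-1}`` on the trait scale.
    """

    item_id: str
    discrimination: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.discrimination) or self.discrimination <= 0:
            raise ValueError(
                f"item {self.item_id!r}: discrimination must be positive, "
                f"got {self.discrimination}"
            )
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.size < 1:
            raise ValueError(f"item {self.item_id!r}: needs >= 1 threshold")
        if not np.all(np.isfinite(thr)):
            raise ValueError(f"item {self.item_id!r}: non-finite threshold")
        if thr.size > 1 and not np.all(np.diff(thr) > 0):
            raise ValueError(
                f"item {self.item_id!r}: thresholds must be strictly increasing"
            )
        object.__setattr__(self, "thresholds", tuple(float(t) for t in thr))

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1

    def to_dict(self) -> dict:
        return {
            "item_id": self.item_id,
            "discrimination": self.discrimination,
            "thresholds": list(self.thresholds),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ItemParameters":
        return cls(
            item_id=str(d["item_id"]),
            discrimination=float(d["discrimination"]),
            thresholds=tuple(float(t) for t in d["thresholds"]),
        )


def save_item_bank(bank: Sequence[ItemParameters], path) -> None:
    """Serialise a list of items to JSON."""
    payload = {"format": "lqrscreen-item-bank", "version": 1,
               "items": [it.to_dict() for it in bank]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_item_bank(path) -> list[ItemParameters]:
    with open(path) as fh:
        payload = json.load(fh)
    return [ItemParameters.from_dict(d) for d in payload["items"]]


@dataclass(frozen=True)
class LatentTraitEstimate:
    """EAP trait estimate for one respondent (standard-normal prior scale)."""

    theta: float
    posterior_sd: float


@dataclass(frozen=True)
class QuadratureConfig:
    """Quadrature grid used for marginalising the latent trait.

    ``equal`` places ``n_nodes`` equally spaced nodes on ``bounds`` with
    trapezoid-style weights times the standard-normal density; the density's
    fast decay at the default bounds makes this spectrally accurate.
    ``gauss-hermite`` uses probabilists' Gauss-Hermite nodes.
    """

    n_nodes: int = 61
    bounds: tuple[float, float] = (-6.0, 6.0)
    scheme: str = "equal"

    def __post_init__(self) -> None:
        if self.n_nodes < 11:
            raise ValueError("n_nodes must be >= 11")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must satisfy lo < hi")
        if self.scheme not in ("equal", "gauss-hermite"):
            raise ValueError(f"unknown quadrature scheme {self.scheme!r}")

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (nodes, weights); weights include the N(0,1) prior, sum 1."""
        if self.scheme == "gauss-hermite":
            x, w = np.polynomial.hermite.hermgauss(self.n_nodes)
            nodes = x * np.sqrt(2.0)
            weights = w / np.sqrt(np.pi)
        else:
            nodes = np.linspace(self.bounds[0], self.bounds[1], self.n_nodes)
            dens = np.exp(-0.5 * nodes**2)
            trap = np.ones(self.n_nodes)
            trap[[0, -1]] = 0.5
            weights = dens * trap
        return nodes, weights / weights.sum()


# ---------------------------------------------------------------------------
# Response matrix container
# ---------------------------------------------------------------------------

class ResponseMatrix:
    """Respondents x items polytomous responses with a missing mask.

    Stored as an integer array (missing entries hold a sentinel) plus a
    boolean mask.  Construct from a pandas DataFrame with
    :meth:`from_dataframe`; NaN / empty cells are treated as missing.
    """

    def __init__(
        self,
        values: np.ndarray,
        missing_mask: np.ndarray,
        item_ids: Sequence[str],
        respondent_ids: Sequence,
        n_categories: Sequence[int] | None = None,
    ) -> None:
        values = np.asarray(values, dtype=np.int64)
        missing_mask = np.asarray(missing_mask, dtype=bool)
        if values.shape != missing_mask.shape or values.ndim != 2:
            raise ValueError("values and missing_mask must be equal 2-D shapes")
        if values.shape[1] != len(item_ids):
            raise ValueError("item_ids length does not match n columns")
        if values.shape[0] != len(respondent_ids):
            raise ValueError("respondent_ids length does not match n rows")
        obs = ~missing_mask
        if np.any(values[obs] < 0):
            raise ValueError("negative category code among observed entries")
        self.values = np.where(missing_mask, _MISSING, values)
        self.missing_mask = missing_mask
        self.item_ids = list(map(str, item_ids))
        self.respondent_ids = list(respondent_ids)
        if n_categories is None:
            # infer K per item from the largest observed code
            ks = []
            for j in range(values.shape[1]):
                col = values[obs[:, j], j] if obs[:, j].any() else np.array([0])
                ks.append(int(col.max()) + 1 if col.size else 2)
            n_categories = [max(k, 2) for k in ks]
        self.n_categories = list(map(int, n_categories))
        for j, k in enumerate(self.n_categories):
            colobs = obs[:, j]
            if colobs.any() and self.values[colobs, j].max() >= k:
                raise ValueError(
                    f"item {self.item_ids[j]!r}: observed code exceeds "
                    f"declared K={k}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, n_categories: Sequence[int] | None = None
    ) -> "ResponseMatrix":
        arr = df.to_numpy(dtype=float)
        mask = ~np.isfinite(arr)
        vals = np.where(mask, 0, arr)
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("non-integer category codes in response table")
        return cls(np.round(vals).astype(np.int64), mask, df.columns, df.index,
                   n_categories)

    def to_dataframe(self) -> pd.DataFrame:
        arr = self.values.astype(float)
        arr[self.missing_mask] = np.nan
        return pd.DataFrame(arr, index=self.respondent_ids,
                            columns=self.item_ids)

    def subset_items(self, items: Sequence[str]) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in items]
        return ResponseMatrix(
            self.values[:, idx], self.missing_mask[:, idx],
            [self.item_ids[i] for i in idx], self.respondent_ids,
            [self.n_categories[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# Probability kernels
# ---------------------------------------------------------------------------

def _cumulative_probs(item: ItemParameters, theta: np.ndarray) -> np.ndarray:
    """Boundary curves P*_k(theta), shape (K-1, ...)."""
    b = np.asarray(item.thresholds)[:, None]
    return expit(item.discrimination * (np.atleast_1d(theta)[None, :] - b))


def category_probabilities(item: ItemParameters, theta) -> np.ndarray:
    """Category probabilities P_k(theta), k = 0..K-1.

    Returns shape (K,) for scalar ``theta``, else (K, len(theta)).  Entries
    are non-negative and sum to 1 (floored at a tiny positive value so the
    observed-response-probability index stays in (0, 1]).
    """
    scalar = np.isscalar(theta) or np.ndim(theta) == 0
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    cum = _cumulative_probs(item, th)
    k1 = item.n_categories
    full = np.vstack([np.ones((1, th.size)), cum, np.zeros((1, th.size))])
    probs = np.clip(full[:-1] - full[1:], 1e-300, 1.0)
    return probs[:, 0] if scalar else probs


def expected_response(item: ItemParameters, theta) -> np.ndarray | float:
    """Model-expected category E[X | theta] on the 0..K-1 coding."""
    probs = category_probabilities(item, theta)
    k = np.arange(item.n_categories, dtype=float)
    if probs.ndim == 1:
        return float(k @ probs)
    return k @ probs


# ---------------------------------------------------------------------------
# EAP scoring
# ---------------------------------------------------------------------------

def _log_likelihood_table(
    bank: Sequence[ItemParameters], nodes: np.ndarray
) -> list[np.ndarray]:
    """Per item: log P_k(node), shape (K_i, Q)."""
    return [np.log(category_probabilities(it, nodes)) for it in bank]


def _posterior_weights(
    values: np.ndarray,
    missing: np.ndarray,
    logp: list[np.ndarray],
    log_prior: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior node weights per respondent and marginal log-lik per row."""
    n, m = values.shape
    ll = np.tile(log_prior, (n, 1))
    for j in range(m):
        obs = ~missing[:, j]
        if obs.any():
            ll[obs] += logp[j][values[obs, j], :]
    norm = logsumexp(ll, axis=1, keepdims=True)
    return np.exp(ll - norm), norm[:, 0]


def eap_scores(
    responses: ResponseMatrix,
    bank: Sequence[ItemParameters],
    quad: QuadratureConfig | None = None,
) -> pd.DataFrame:
    """EAP trait mean and posterior SD for every respondent.

    All-missing rows fall back to the prior (theta 0, SD 1).
    """
    quad = quad or QuadratureConfig()
    nodes, weights = quad.grid()
    logp = _log_likelihood_table(bank, nodes)
    post, _ = _posterior_weights(responses.values, responses.missing_mask,
                                 logp, np.log(weights))
    mean = post @ nodes
    var = post @ nodes**2 - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    return pd.DataFrame(
        {"theta": mean, "posterior_sd": sd}, index=responses.respondent_ids
    )


def estimate_theta_eap(
    row,
    bank: Sequence[ItemParameters],
    quad: QuadratureConfig | None = None,
) -> LatentTraitEstimate:
    """EAP estimate for a single response vector (NaN = missing)."""
    arr = np.asarray(row, dtype=float).reshape(1, -1)
    if arr.shape[1] != len(bank):
        raise ValueError(
            f"row has {arr.shape[1]} entries but bank has {len(bank)} items"
        )
    rm = ResponseMatrix.from_dataframe(
        pd.DataFrame(arr, columns=[it.item_id for it in bank]),
        n_categories=[it.n_categories for it in bank],
    )
    df = eap_scores(rm, bank, quad)
    return LatentTraitEstimate(float(df["theta"].iloc[0]),
                               float(df["posterior_sd"].iloc[0]))


# ---------------------------------------------------------------------------
# MML-EM estimation
# ---------------------------------------------------------------------------

def _item_nll_and_grad(u: np.ndarray, r: np.ndarray, nodes: np.ndarray):
    """Expected negative complete-data log-lik of one item and its gradient.

    Parameterised as u = (log a, b_1, log gap_2, ..., log gap_{K-1}) so the
    slope stays positive and thresholds stay ordered.
    """
    k_minus_1 = r.shape[0] - 1
    a = np.exp(u[0])
    gaps = np.exp(u[2:])
    b = u[1] + np.concatenate([[0.0], np.cumsum(gaps)])  # (K-1,)
    z = a * (nodes[None, :] - b[:, None])                # (K-1, Q)
    pstar = expit(z)
    q = nodes.size
    full = np.vstack([np.ones((1, q)), pstar, np.zeros((1, q))])
    probs = np.clip(full[:-1] - full[1:], 1e-12, None)   # (K, Q)
    nll = -np.sum(r * np.log(probs))

    # dF/dP*_k = -(r_k / P_k - r_{k-1} / P_{k-1}),  k = 1..K-1
    ratio = r / probs
    dpstar = -(ratio[1:] - ratio[:-1])                   # (K-1, Q)
    s = pstar * (1.0 - pstar)
    common = dpstar * s
    da = np.sum(common * (nodes[None, :] - b[:, None]))
    db = -a * common.sum(axis=1)                         # (K-1,)
    grad = np.empty_like(u)
    grad[0] = da * a                                     # chain: d/dlog a
    grad[1] = db.sum()
    if k_minus_1 > 1:
        # b_k depends on gap_j for j <= k-1 (1-indexed gaps start at 2)
        tail = np.cumsum(db[::-1])[::-1][1:]             # sum_{k>=j} db_k
        grad[2:] = tail * gaps
    return nll, grad


def _initial_item_params(values, missing, j, k, item_id) -> np.ndarray:
    """Start values from marginal cumulative proportions."""
    col = values[~missing[:, j], j]
    props = np.array([(col >= c).mean() for c in range(1, k)])
    props = np.clip(props, 1e-3, 1 - 1e-3)
    b = -np.log(props / (1 - props))  # logit^{-1} at a = 1
    b = np.maximum.accumulate(b)
    gaps = np.clip(np.diff(b), 0.05, None)
    u = np.empty(1 + (k - 1))
    u[0] = 0.0  # log a = 0
    u[1] = b[0]
    if k > 2:
        u[2:] = np.log(gaps)
    return u


@dataclass
class GRMResults:
    """Fit results of a :class:`GradedResponseModel`.

    Attributes
    ----------
    item_parameters : list of ItemParameters
        Estimated discriminations and thresholds.
    llf : float
        Marginal log-likelihood at the final iteration.
    loglik_trace : list of float
        Marginal log-likelihood after each EM iteration (non-decreasing).
    converged : bool
    """

    model: "GradedResponseModel"
    item_parameters: list[ItemParameters]
    llf: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    def eap(self, responses: ResponseMatrix | None = None) -> pd.DataFrame:
        """Score respondents (training data by default) by EAP."""
        rm = responses if responses is not None else self.model.responses
        return eap_scores(rm, self.item_parameters, self.model.quad)

    def summary(self) -> str:
        lines = [
            "Graded Response Model (MML-EM)",
            "=" * 58,
            f"Respondents: {self.model.responses.shape[0]:>6}   "
            f"Items: {self.model.responses.shape[1]}",
            f"Log-likelihood: {self.llf:.3f}   Iterations: {self.n_iter}   "
            f"Converged: {self.converged}",
            "-" * 58,
            f"{'item':<16}{'a':>8}  thresholds",
        ]
        for it in self.item_parameters:
            thr = ", ".join(f"{t:.3f}" for t in it.thresholds)
            lines.append(f"{it.item_id:<16}{it.discrimination:>8.3f}  [{thr}]")
        return "\n".join(lines)

    def save(self, path) -> None:
        save_item_bank(self.item_parameters, path)


class GradedResponseModel:
    """Unidimensional GRM for one questionnaire scale.

    Parameters
    ----------
    responses : ResponseMatrix or DataFrame
        Integer category codes 0..K-1; NaN = missing.  Missing entries are
        skipped in the likelihood.
    quad : QuadratureConfig, optional
        Latent-trait integration grid (default: 61 equally spaced nodes on
        [-6, 6] under the standard-normal prior).

    Examples
    --------
    >>> model = GradedResponseModel(responses_df)
    >>> res = model.fit()
    >>> res.item_parameters[0].discrimination  # doctest: +SKIP
    """

    def __init__(self, responses, quad: QuadratureConfig | None = None):
        if isinstance(responses, pd.DataFrame):
            responses = ResponseMatrix.from_dataframe(responses)
        if not isinstance(responses, ResponseMatrix):
            raise TypeError("responses must be a ResponseMatrix or DataFrame")
        if responses.shape[0] == 0 or responses.shape[1] == 0:
            raise ValueError("empty response matrix")
        self.responses = responses
        self.quad = quad or QuadratureConfig()

    def fit(self, max_iter: int = 500, tol: float = 1e-6) -> GRMResults:
        """Estimate item parameters by MML-EM.

        Stops when the relative marginal log-likelihood improvement falls
        below ``tol`` or after ``max_iter`` EM iterations.

        Raises
        ------
        EstimationError
            If any item has fewer than two observed categories.
        """
        rm = self.responses
        values, missing = rm.values, rm.missing_mask
        n, m = rm.shape
        for j in range(m):
            col = values[~missing[:, j], j]
            if np.unique(col).size < 2:
                raise EstimationError(
                    f"item {rm.item_ids[j]!r} has fewer than two observed "
                    "categories; it cannot be estimated"
                )
        nodes, weights = self.quad.grid()
        log_prior = np.log(weights)

        u = [
            _initial_item_params(values, missing, j, rm.n_categories[j],
                                 rm.item_ids[j])
            for j in range(m)
        ]
        params = [self._decode(u[j], rm.item_ids[j]) for j in range(m)]

        trace: list[float] = []
        prev_ll = -np.inf
        converged = False
        for it in range(max_iter):
            logp = _log_likelihood_table(params, nodes)
            post, row_ll = _posterior_weights(values, missing, logp, log_prior)
            ll = float(row_ll.sum())
            trace.append(ll)
            if ll + 1e-8 < prev_ll:  # EM must not decrease
                warnings.warn("EM log-likelihood decreased; stopping")
                break
            if it > 0 and abs(ll - prev_ll) < tol * abs(prev_ll):
                converged = True
                break
            prev_ll = ll
            # M-step, item by item
            for j in range(m):
                k = rm.n_categories[j]
                obs = ~missing[:, j]
                r = np.zeros((k, nodes.size))
                for c in range(k):
                    sel = obs & (values[:, j] == c)
                    if sel.any():
                        r[c] = post[sel].sum(axis=0)
                res = minimize(
                    _item_nll_and_grad, u[j], args=(r, nodes), jac=True,
                    method="L-BFGS-B",
                )
                u[j] = res.x
                params[j] = self._decode(u[j], rm.item_ids[j])

        # final log-likelihood under the last parameter update
        logp = _log_likelihood_table(params, nodes)
        _, row_ll = _posterior_weights(values, missing, logp, log_prior)
        llf = float(row_ll.sum())
        if not trace or llf >= trace[-1] - 1e-8:
            trace.append(llf)
        else:
            llf = trace[-1]
        return GRMResults(self, params, llf, trace, len(trace) - 1, converged)

    @staticmethod
    def _decode(u: np.ndarray, item_id: str) -> ItemParameters:
        a = float(np.exp(u[0]))
        b = u[1] + np.concatenate([[0.0], np.cumsum(np.exp(u[2:]))])
        return ItemParameters(item_id, a, tuple(b))

    def loglike(self, bank: Sequence[ItemParameters]) -> float:
        """Marginal log-likelihood of the training data under ``bank``."""
        nodes, weights = self.quad.grid()
        logp = _log_likelihood_table(bank, nodes)
        _, row_ll = _posterior_weights(
            self.responses.values, self.responses.missing_mask, logp,
            np.log(weights),
        )
        return float(row_ll.sum())


def fit_grm(
    responses,
    quad: QuadratureConfig | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[list[ItemParameters], float]:
    """Functional wrapper: fit a GRM and return (item bank, log-likelihood)."""
    res = GradedResponseModel(responses, quad).fit(max_iter=max_iter, tol=tol)
    return res.item_parameters, res.llf
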