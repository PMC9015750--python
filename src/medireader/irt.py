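"""Three-parameter-logistic (3PL) item response theory for literacy screening.

The screening test models the probability that person ``j`` answers item
``i`` correctly as

    P_ij = c_i + (1 - c_i) / (1 + exp(-a_i (theta_j - b_i)))

with discrimination ``a``, difficulty ``b`` and guessing lower asymptote
``c``. Abilities ``theta`` carry a standard-normal population prior, so a
score of 0 is average (50th percentile): scores above 0 classify as high
literacy, below 0 as low.

The module provides

* closed-form item functions (:func:`prob_correct`, :func:`item_information`),
* EAP ability scoring by fixed-grid quadrature (:func:`estimate_ability_eap`),
* marginal-maximum-likelihood calibration by EM (:class:`ThreePLModel` /
  :class:`ThreePLResults`, or the functional wrapper :func:`calibrate_3pl_em`),
* information-based test shortening (:func:`shorten_test`), and
* the two-level literacy classification (:func:`classify_literacy`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "Item", "ResponseMatrix", "AbilityEstimate", "QuadratureGrid",
    "prob_correct", "item_information", "estimate_ability_eap",
    "ThreePLModel", "ThreePLResults", "calibrate_3pl_em",
    "shorten_test", "classify_literacy",
]


@dataclass(frozen=True)
class Item:
    """3PL item parameters: discrimination a, difficulty b, guessing c."""

    id: str
    a: float
    b: float
    c: float = 0.0

    def __post_init__(self):
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError(f"item {self.id!r}: a and b must be finite")
        if not (0.0 <= self.c < 1.0):
            raise ValueError(f"item {self.id!r}: c must lie in [0, 1)")


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed quadrature grid with standard-normal prior weights."""

    lo: float = -6.0
    hi: float = 6.0
    n: int = 61

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n)

    @property
    def weights(self) -> np.ndarray:
        w = norm.pdf(self.nodes)
        return w / w.sum()


@dataclass(frozen=True)
class AbilityEstimate:
    """Posterior summary of a person's latent ability theta."""

    theta: float
    se: float
    n_items: int


def prob_correct(item: Item, theta) -> np.ndarray | float:
    """3PL probability of a correct response; vectorized over ``theta``."""
    p = item.c + (1.0 - item.c) * expit(item.a * (np.asarray(theta, float) - item.b))
    return float(p) if np.ndim(theta) == 0 else p


def item_information(item: Item, theta) -> np.ndarray | float:
    """Fisher information of one 3PL item at ability ``theta``.

    I(theta) = a^2 * (Q/P) * (P - c)^2 / (1 - c)^2; reduces to a^2 P Q for c=0.
    """
    p = item.c + (1.0 - item.c) * expit(item.a * (np.asarray(theta, float) - item.b))
    info = item.a ** 2 * ((1.0 - p) / p) * (p - item.c) ** 2 / (1.0 - item.c) ** 2
    return float(info) if np.ndim(theta) == 0 else info


def estimate_ability_eap(responses, items: list[Item],
                         grid: QuadratureGrid = QuadratureGrid()) -> AbilityEstimate:
    """EAP estimate of theta under the standard-normal prior.

    ``responses`` is a per-item 0/1 sequence aligned with ``items``; entries
    may be None/NaN for omitted items. With zero (effective) items the
    posterior is the prior: theta=0, se=1.
    """
    responses = list(responses)
    if len(responses) != len(items):
        raise ValueError(
            f"got {len(responses)} responses for {len(items)} items")
    nodes, weights = grid.nodes, grid.weights
    log_post = np.log(weights)
    n_used = 0
    for u, item in zip(responses, items):
        if u is None or (isinstance(u, float) and math.isnan(u)):
            continue
        u = int(u)
        if u not in (0, 1):
            raise ValueError(f"response must be 0/1/missing, got {u!r}")
        p = prob_correct(item, nodes)
        log_post += np.log(p) if u == 1 else np.log1p(-p)
        n_used += 1
    if n_used == 0:
        return AbilityEstimate(theta=0.0, se=1.0, n_items=0)
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    mean = float(post @ nodes)
    var = float(post @ (nodes - mean) ** 2)
    return AbilityEstimate(theta=mean, se=math.sqrt(max(var, 1e-300)),
                           n_items=n_used)


def classify_literacy(est: AbilityEstimate) -> str:
    """Two-level literacy call: theta >= 0 -> "high", theta < 0 -> "low".

    Zero is the population average; the boundary case is classified high.
    """
    return "high" if est.theta >= 0.0 else "low"


class ResponseMatrix:
    """Persons x items binary response data; missing entries allowed (NaN)."""

    def __init__(self, persons: list[str], items: list[str], values):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(persons), len(items)):
            raise ValueError("values shape does not match persons x items")
        obs = values[~np.isnan(values)]
        if obs.size and not np.isin(obs, [0.0, 1.0]).all():
            raise ValueError("non-missing entries must be 0 or 1")
        if len(set(persons)) != len(persons) or len(set(items)) != len(items):
            raise ValueError("person and item ids must be unique")
        self.persons = list(persons)
        self.items = list(items)
        self.values = values

    @property
    def shape(self):
        return self.values.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, person_col: str = "person") -> "ResponseMatrix":
        df = df.set_index(person_col) if person_col in df.columns else df
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   df.to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path: str | Path, person_col: str = "person") -> "ResponseMatrix":
        return cls.from_dataframe(pd.read_csv(path), person_col=person_col)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.persons, columns=self.items)


@dataclass
class EMConfig:
    """EM settings for marginal 3PL calibration.

    ``c_prior`` is a Beta(alpha, beta) prior on the guessing parameter
    (Bayes-modal estimation; the (5, 17) default has its mode at c = 0.2 and
    is the textbook remedy for the weakly identified c-a trade-off). Set it
    to None for pure maximum likelihood, in which case the fit log is the
    marginal log-likelihood itself.
    """

    max_iter: int = 500
    tol: float = 1e-5
    grid: QuadratureGrid = field(default_factory=QuadratureGrid)
    a_bounds: tuple[float, float] = (0.05, 5.0)
    b_bounds: tuple[float, float] = (-6.0, 6.0)
    c_bounds: tuple[float, float] = (0.0, 0.5)
    c_prior: tuple[float, float] | None = (5.0, 17.0)


class ThreePLModel:
    """Marginal-maximum-likelihood 3PL model for a binary response matrix.

    Ability is integrated out against the standard-normal prior on a fixed
    quadrature grid; item parameters are estimated by EM. Columns that are
    constant among observed entries carry no information about (a, b, c) and
    are excluded from the fit with a warning.
    """

    def __init__(self, responses: ResponseMatrix):
        if responses.shape[0] < 2 or responses.shape[1] < 2:
            raise ValueError("calibration needs at least 2 persons and 2 items")
        self.responses = responses
        self.excluded_items: list[str] = []
        keep = []
        for j, item_id in enumerate(responses.items):
            col = responses.values[:, j]
            obs = col[~np.isnan(col)]
            if obs.size == 0 or obs.min() == obs.max():
                self.excluded_items.append(item_id)
                logger.warning("excluding degenerate item %r (constant column)",
                               item_id)
            else:
                keep.append(j)
        if not keep:
            raise ValueError("no non-degenerate items to calibrate")
        self._cols = np.array(keep)
        self.item_ids = [responses.items[j] for j in keep]
        self._U = responses.values[:, self._cols]

    # -- EM machinery ---------------------------------------------------------

    @staticmethod
    def _neg_item_loglik(params, nodes, r, n, c_prior=None):
        a, b, c = params
        p = c + (1.0 - c) * expit(a * (nodes - b))
        p = np.clip(p, 1e-10, 1.0 - 1e-10)
        f = -(r * np.log(p) + (n - r) * np.log1p(-p)).sum()
        # gradient of the expected complete-data negative log-likelihood
        w = (r - n * p) / (p * (1.0 - p))
        logistic = (p - c) / (1.0 - c)
        dp_da = (1.0 - c) * logistic * (1.0 - logistic) * (nodes - b)
        dp_db = -(1.0 - c) * logistic * (1.0 - logistic) * a
        dp_dc = 1.0 - logistic
        grad = -np.array([(w * dp_da).sum(), (w * dp_db).sum(), (w * dp_dc).sum()])
        if c_prior is not None:
            alpha, beta = c_prior
            f -= (alpha - 1) * np.log(c) + (beta - 1) * np.log(1.0 - c)
            grad[2] += -(alpha - 1) / c + (beta - 1) / (1.0 - c)
        return f, grad

    def _marginal_loglik(self, A, B, C, nodes, weights):
        P = C[:, None] + (1 - C[:, None]) * expit(A[:, None] * (nodes[None, :] - B[:, None]))
        P = np.clip(P, 1e-10, 1 - 1e-10)
        U = self._U
        obs = ~np.isnan(U)
        U0 = np.where(obs, U, 0.0)
        # log L_jk = sum_i u log P + (1-u) log(1-P) over observed entries
        ll = (U0 * obs) @ np.log(P) + ((1 - U0) * obs) @ np.log1p(-P)
        m = ll.max(axis=1, keepdims=True)
        marg = m[:, 0] + np.log(np.exp(ll - m) @ weights)
        return float(marg.sum()), ll

    def fit(self, config: EMConfig | None = None, verbose: bool = False) -> "ThreePLResults":
        cfg = config or EMConfig()
        nodes, weights = cfg.grid.nodes, cfg.grid.weights
        U, obs = self._U, ~np.isnan(self._U)
        U0 = np.where(obs, U, 0.0)
        n_items = U.shape[1]

        # starting values: a=1, b from the item's observed proportion correct
        pbar = np.clip(np.nansum(U, axis=0) / obs.sum(axis=0), 0.02, 0.98)
        A = np.ones(n_items)
        B = np.clip(-norm.ppf(pbar), *cfg.b_bounds)
        C = np.full(n_items, 0.1)

        if cfg.c_prior is not None:
            C = np.clip(C, 1e-4, None)
            c_lo = max(cfg.c_bounds[0], 1e-4)
        else:
            c_lo = cfg.c_bounds[0]
        bounds = [cfg.a_bounds, cfg.b_bounds, (c_lo, cfg.c_bounds[1])]

        def log_prior():
            if cfg.c_prior is None:
                return 0.0
            alpha, beta = cfg.c_prior
            return float(((alpha - 1) * np.log(C)
                          + (beta - 1) * np.log(1.0 - C)).sum())

        loglik_path: list[float] = []        # EM objective (see EMConfig)
        marginal_path: list[float] = []
        converged = False
        for it in range(cfg.max_iter):
            ll, ll_jk = self._marginal_loglik(A, B, C, nodes, weights)
            marginal_path.append(ll)
            loglik_path.append(ll + log_prior())
            if verbose:
                logger.info("EM iter %d: objective %.6f", it, loglik_path[-1])
            if it > 0 and abs(loglik_path[-1] - loglik_path[-2]) < cfg.tol:
                converged = True
                break
            # E-step: posterior weights over the grid per person
            m = ll_jk.max(axis=1, keepdims=True)
            W = np.exp(ll_jk - m) * weights
            W /= W.sum(axis=1, keepdims=True)
            # expected attempted / correct counts at each node, per item
            n_ik = W.T @ obs                   # (nodes, items)
            r_ik = W.T @ (U0 * obs)
            # M-step: independent 3-parameter problems, warm-started
            for i in range(n_items):
                x0 = np.array([A[i], B[i], C[i]])
                f0, _ = self._neg_item_loglik(x0, nodes, r_ik[:, i],
                                              n_ik[:, i], cfg.c_prior)
                res = minimize(self._neg_item_loglik, x0, jac=True,
                               args=(nodes, r_ik[:, i], n_ik[:, i], cfg.c_prior),
                               method="L-BFGS-B", bounds=bounds)
                if res.fun <= f0:              # keep EM ascent exact
                    A[i], B[i], C[i] = res.x
        items = [Item(self.item_ids[i], float(A[i]), float(B[i]), float(C[i]))
                 for i in range(n_items)]
        return ThreePLResults(model=self, items=items,
                              loglik_path=np.array(loglik_path),
                              marginal_loglik_path=np.array(marginal_path),
                              converged=converged, config=cfg)


@dataclass
class ThreePLResults:
    """Fitted 3PL calibration: item estimates, fit log and person scoring.

    ``loglik_path`` is the objective the EM ascends (marginal log-likelihood
    plus the log prior on c when a prior is configured; the marginal
    log-likelihood itself under pure ML) and is non-decreasing across
    iterations. ``marginal_loglik_path`` is always the marginal
    log-likelihood.
    """

    model: ThreePLModel
    items: list[Item]
    loglik_path: np.ndarray
    marginal_loglik_path: np.ndarray
    converged: bool
    config: EMConfig

    @property
    def loglik(self) -> float:
        return float(self.marginal_loglik_path[-1])

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"a": [it.a for it in self.items],
             "b": [it.b for it in self.items],
             "c": [it.c for it in self.items]},
            index=[it.id for it in self.items])

    def score_persons(self, grid: QuadratureGrid | None = None) -> pd.DataFrame:
        """EAP ability, posterior SD and literacy level for every person."""
        grid = grid or self.config.grid
        rm = self.model.responses
        rows = []
        for pi, person in enumerate(rm.persons):
            resp = [rm.values[pi, j] for j in self.model._cols]
            resp = [None if np.isnan(v) else int(v) for v in resp]
            est = estimate_ability_eap(resp, self.items, grid)
            rows.append((person, est.theta, est.se, est.n_items,
                         classify_literacy(est)))
        return pd.DataFrame(rows, columns=["person", "theta", "se", "n_items",
                                           "literacy"]).set_index("person")

    def summary(self) -> str:
        df = self.params_frame()
        lines = [
            "3PL Marginal Maximum Likelihood Calibration",
            "=" * 46,
            f"persons: {self.model.responses.shape[0]}"
            f"   items fitted: {len(self.items)}"
            f"   excluded: {len(self.model.excluded_items)}",
            f"log-likelihood: {self.loglik:.3f}"
            f"   EM iterations: {len(self.loglik_path)}"
            f"   converged: {self.converged}",
            "-" * 46,
            df.to_string(float_format=lambda x: f"{x:8.4f}"),
        ]
        if self.model.excluded_items:
            lines.append("-" * 46)
            lines.append("excluded (degenerate): "
                         + ", ".join(self.model.excluded_items))
        return "\n".join(lines)


def calibrate_3pl_em(matrix: ResponseMatrix,
                     config: EMConfig | None = None) -> ThreePLResults:
    """Functional wrapper: fit the 3PL model by EM and return the results."""
    return ThreePLModel(matrix).fit(config)


def load_items(path: str | Path) -> list[Item]:
    """Read an item bank from CSV (columns id,a,b,c) or a JSON list."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        import json
        records = json.loads(path.read_text(encoding="utf-8"))
    else:
        records = pd.read_csv(path).to_dict("records")
    return [Item(str(r["id"]), float(r["a"]), float(r["b"]),
                 float(r.get("c", 0.0))) for r in records]


def save_items(items: list[Item], path: str | Path) -> None:
    pd.DataFrame([{"id": it.id, "a": it.a, "b": it.b, "c": it.c}
                  for it in items]).to_csv(path, index=False)


def shorten_test(items: list[Item], n: int,
                 theta_grid: QuadratureGrid = QuadratureGrid(),
                 a_min: float = 0.2) -> list[str]:
    """Pick the ``n`` most informative items for a short-form test.

    Items whose discrimination does not exceed ``a_min`` cannot separate
    high- from low-ability respondents and are removed first. The remainder
    are selected greedily to maximize the mean total information over the
    ability grid; information is additive across items, so the greedy
    selection attains the best subset exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(items):
        raise ValueError(f"n={n} exceeds the {len(items)}-item bank")
    nodes = theta_grid.nodes
    survivors = [it for it in items if it.a > a_min]
    if len(survivors) < len(items):
        dropped = [it.id for it in items if it.a <= a_min]
        logger.info("removed %d non-discriminating items (a <= %g): %s",
                    len(dropped), a_min, dropped)
    mean_info = {it.id: float(np.mean(item_information(it, nodes)))
                 for it in survivors}
    selected: list[str] = []
    pool = list(survivors)
    while pool and len(selected) < n:
        best = max(pool, key=lambda it: (mean_info[it.id], it.id))
        selected.append(best.id)
        pool.remove(best)
    return selected
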