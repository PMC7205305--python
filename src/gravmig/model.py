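"""The cross-scale spatial interaction model.

A gravity-type logistic model predicts ``v_ij``, the five-year proportion of
origin unit *i*'s people migrating to destination unit *j*, from pairwise
covariates::

    logit(v_ij) = beta_0 + beta_1 * DIST_ij + beta_2 * POP_i + beta_3 * POP_j + ...

Because migration counts are observed only at a coarser level, fine-pair
proportions are aggregated to coarse pairs by a population-weighted average
over origins,

    P_IJ = sum_{i in I} N_i * (sum_{j in J} v_ij) / sum_{i in I} N_i,

and the observed coarse counts ``M_IJ`` out of origin sample sizes ``N_I``
enter an independent-binomial log-likelihood over ordered coarse pairs
I != J.  Slopes carry Cauchy(0, 2.5) priors and the intercept Cauchy(0, 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import expit, gammaln

from .covariates import PairDesign

# linear predictors are clipped here so the inverse logit never rounds to 0 or 1
_ETA_MAX = 35.0


@dataclass(frozen=True)
class PriorSpec:
    """Independent Cauchy priors centred at 0: scale 2.5 for slopes, 10 for
    the intercept (weakly informative for standardized covariates)."""

    slope_scale: float = 2.5
    intercept_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.slope_scale <= 0 or self.intercept_scale <= 0:
            raise ValueError("prior scales must be positive")

    def scales(self, n_params: int) -> np.ndarray:
        s = np.full(n_params, self.slope_scale)
        s[0] = self.intercept_scale
        return s


class CoarseFlows:
    """Observed coarse-level migrant counts and origin sample sizes.

    ``counts`` has one row per ordered coarse pair (origin, dest, count),
    I != J; ``sizes`` maps each coarse origin id to the number of sampled
    persons N_I there.
    """

    def __init__(self, counts: pd.DataFrame, sizes: pd.Series):
        counts = counts.reset_index(drop=True)
        if (counts["origin"] == counts["dest"]).any():
            raise ValueError("coarse flows must not contain self-pairs")
        if (counts["count"] < 0).any():
            raise ValueError("negative flow count")
        sizes = sizes.astype(int)
        if (sizes <= 0).any():
            raise ValueError("origin sample sizes must be positive")
        out_total = counts.groupby("origin")["count"].sum()
        for origin, total in out_total.items():
            if total > sizes.get(origin, 0):
                raise ValueError(f"outflow from {origin} exceeds its sample size")
        self.counts = counts
        self.sizes = sizes

    def __len__(self) -> int:
        return len(self.counts)

    def aligned_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(M_IJ, N_I) arrays aligned to the rows of ``counts``."""
        m = self.counts["count"].to_numpy(dtype=float)
        n = self.sizes.loc[self.counts["origin"]].to_numpy(dtype=float)
        return m, n

    def to_csv(self, flows_path: str | Path, sizes_path: str | Path,
               header: str | None = None) -> None:
        with open(flows_path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            self.counts.rename(columns={"origin": "origin_id", "dest": "dest_id"}
                               ).to_csv(fh, index=False)
        with open(sizes_path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            self.sizes.rename_axis("origin_id").rename("n").to_csv(fh)

    @classmethod
    def from_csv(cls, flows_path: str | Path, sizes_path: str | Path) -> "CoarseFlows":
        counts = pd.read_csv(flows_path, comment="#", dtype={"origin_id": str, "dest_id": str})
        counts = counts.rename(columns={"origin_id": "origin", "dest_id": "dest"})
        sizes = pd.read_csv(sizes_path, comment="#", dtype={"origin_id": str}
                            ).set_index("origin_id")["n"]
        return cls(counts, sizes)


def predict_vij(beta, design: PairDesign) -> np.ndarray:
    """Fine-pair migration proportions: inverse logit of the linear predictor.

    Returns one value per ordered pair row of the design, each strictly
    inside (0, 1).
    """
    beta = np.asarray(beta, dtype=float)
    X = design.matrix()
    if beta.shape != (X.shape[1],):
        raise ValueError(
            f"coefficient length {beta.size} does not match design with "
            f"{X.shape[1]} parameters")
    eta = np.clip(X @ beta, -_ETA_MAX, _ETA_MAX)
    return expit(eta)


def proportion_matrix(design: PairDesign, v: np.ndarray) -> pd.DataFrame:
    """Pivot a pair-row proportion vector into an origin × destination matrix
    (diagonal 0; fine self-pairs are undefined)."""
    ids = pd.unique(pd.concat([design.frame["origin"], design.frame["dest"]]))
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    mat.values[
        mat.index.get_indexer(design.frame["origin"]),
        mat.columns.get_indexer(design.frame["dest"]),
    ] = v
    return mat


def aggregate_proportions(v: pd.DataFrame, units: pd.DataFrame,
                          partition: dict | pd.Series | None = None,
                          denominator: str = "origin") -> pd.DataFrame:
    """Population-weighted aggregation of fine-pair proportions to coarse pairs.

    ``v`` is a fine origin × destination proportion matrix (diagonal
    ignored); ``partition`` maps fine ids to coarse group ids (defaults to
    the unit table's ``coarse_id``).  With the default ``denominator
    ("origin")`` the weight normalises by the origin group's population, so
    P_IJ is the population-weighted mean over origins i of the total
    proportion migrating to any unit of J.  ``denominator="literal"``
    additionally divides by the number of destination units, the equation as
    printed; it no longer yields a proportion of I's population and exists
    for auditability.
    """
    if denominator not in {"origin", "literal"}:
        raise ValueError("denominator must be 'origin' or 'literal'")
    units = units.set_index("id", drop=False)
    if partition is None:
        part = units["coarse_id"]
    else:
        part = pd.Series(dict(partition) if isinstance(partition, dict) else partition)
    ids = list(v.index)
    missing = [u for u in ids if u not in part.index]
    if missing:
        raise ValueError(f"units missing from partition: {missing[:5]}")
    groups = part.loc[ids]
    labels = list(pd.unique(groups))
    gpos = {g: k for k, g in enumerate(labels)}
    B = np.zeros((len(ids), len(labels)))
    B[np.arange(len(ids)), [gpos[g] for g in groups]] = 1.0
    N = units.loc[ids, "population"].to_numpy(dtype=float)
    denom = B.T @ N
    if (denom <= 0).any():
        raise ValueError("empty or zero-population coarse unit")
    V = v.to_numpy(dtype=float).copy()
    np.fill_diagonal(V, 0.0)
    numer = B.T @ (N[:, None] * V) @ B
    P = numer / denom[:, None]
    if denominator == "literal":
        P = P / B.sum(axis=0)[None, :]
    return pd.DataFrame(P, index=labels, columns=labels)


def binomial_loglik(P, flows: CoarseFlows, include_constant: bool = False,
                    on_invalid: str = "error") -> float:
    """Independent-binomial log-likelihood over ordered coarse pairs I != J.

    ``P`` is either a coarse proportion matrix (DataFrame) or a vector
    aligned to ``flows.counts`` rows.  The combinatorial constant
    ln C(N_I, M_IJ) is added via log-gamma only when ``include_constant`` —
    it does not depend on the coefficients and cancels in MCMC.
    ``on_invalid`` governs proportions outside (0, 1): ``"error"`` raises,
    ``"neginf"`` returns -inf (used to reject such proposals).
    """
    if on_invalid not in {"error", "neginf"}:
        raise ValueError("on_invalid must be 'error' or 'neginf'")
    m, n = flows.aligned_arrays()
    if isinstance(P, pd.DataFrame):
        p = P.to_numpy()[
            P.index.get_indexer(flows.counts["origin"]),
            P.columns.get_indexer(flows.counts["dest"]),
        ]
    else:
        p = np.asarray(P, dtype=float)
        if p.shape != m.shape:
            raise ValueError("proportion vector does not align with flow rows")
    if (p <= 0).any() or (p >= 1).any():
        if on_invalid == "neginf":
            return -np.inf
        raise ValueError("coarse proportion outside (0, 1)")
    ll = float(np.sum(m * np.log(p) + (n - m) * np.log1p(-p)))
    if include_constant:
        ll += float(np.sum(gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)))
    return ll


def cauchy_logprior(beta, priors: PriorSpec) -> float:
    """Sum of Cauchy(0, s) log-densities over all coefficients."""
    beta = np.asarray(beta, dtype=float)
    s = priors.scales(beta.size)
    return float(np.sum(-np.log(np.pi * s) - np.log1p((beta / s) ** 2)))


def log_posterior(beta, design: PairDesign, units: pd.DataFrame,
                  partition, flows: CoarseFlows,
                  priors: PriorSpec = PriorSpec()) -> float:
    """Reference composition: likelihood of the aggregated proportions plus
    the Cauchy log-prior (constant-free).  For repeated evaluation inside
    MCMC use :class:`CrossScalePosterior`, which precomputes the pieces."""
    v = predict_vij(beta, design)
    P = aggregate_proportions(proportion_matrix(design, v), units, partition)
    ll = binomial_loglik(P, flows, on_invalid="neginf")
    return ll + cauchy_logprior(beta, priors)


class CrossScalePosterior:
    """Precomputed log-posterior for MCMC.

    Caches the design matrix and a sparse pair-to-coarse-pair aggregation
    operator so each evaluation is one matrix-vector product, one inverse
    logit, one sparse product and the binomial terms.
    """

    def __init__(self, design: PairDesign, units: pd.DataFrame, flows: CoarseFlows,
                 partition: dict | pd.Series | None = None,
                 priors: PriorSpec = PriorSpec()):
        self.design = design
        self.priors = priors
        self.flows = flows
        self.X = design.matrix()
        units_ix = units.set_index("id", drop=False)
        if partition is None:
            part = units_ix["coarse_id"]
        else:
            part = pd.Series(dict(partition) if isinstance(partition, dict) else partition)
        frame = design.frame
        g_origin = part.loc[frame["origin"]].to_numpy()
        g_dest = part.loc[frame["dest"]].to_numpy()
        group_pop = units_ix.groupby(part)["population"].sum()
        pair_index = {(o, d): r for r, (o, d) in
                      enumerate(flows.counts[["origin", "dest"]].itertuples(index=False, name=None))}
        rows, cols, weights = [], [], []
        N_i = frame["N_i"].to_numpy(dtype=float)
        for col, (gi, gj) in enumerate(zip(g_origin, g_dest)):
            r = pair_index.get((gi, gj))
            if r is None:
                continue  # within-group pair or pair absent from the observations
            rows.append(r)
            cols.append(col)
            weights.append(N_i[col] / group_pop[gi])
        self.S = sparse.csr_matrix(
            (weights, (rows, cols)), shape=(len(flows), len(frame)))
        self.m, self.n = flows.aligned_arrays()
        self._prior_scales = priors.scales(self.X.shape[1])
        self._max_group_size = int(pd.Series(part).value_counts().max())

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def feasible_center(self, margin: float = 0.25) -> np.ndarray:
        """A coefficient vector safely inside the feasible region.

        Zero slopes with an intercept low enough that even the largest
        destination group's summed proportion stays below ``margin``; used
        to anchor dispersed chain starting points."""
        from scipy.special import logit
        beta = np.zeros(self.n_params)
        beta[0] = logit(margin / self._max_group_size)
        return beta

    def coarse_proportions(self, beta) -> np.ndarray:
        eta = np.clip(self.X @ np.asarray(beta, dtype=float), -_ETA_MAX, _ETA_MAX)
        return self.S @ expit(eta)

    def loglik(self, beta) -> float:
        p = self.coarse_proportions(beta)
        if (p <= 0).any() or (p >= 1).any():
            return -np.inf
        return float(np.sum(self.m * np.log(p) + (self.n - self.m) * np.log1p(-p)))

    def logprior(self, beta) -> float:
        b = np.asarray(beta, dtype=float)
        s = self._prior_scales
        return float(np.sum(-np.log(np.pi * s) - np.log1p((b / s) ** 2)))

    def __call__(self, beta) -> float:
        ll = self.loglik(beta)
        if not np.isfinite(ll):
            return -np.inf
        return ll + self.logprior(beta)

    def map_estimate(self) -> np.ndarray:
        """Posterior mode found by L-BFGS from the feasible center.

        Used to anchor chain starting points in the dominant posterior
        basin; falls back to the feasible center if optimisation fails."""
        from scipy.optimize import minimize

        def objective(b):
            val = self(b)
            return 1e12 if not np.isfinite(val) else -val

        x0 = self.feasible_center()
        res = minimize(objective, x0, method="L-BFGS-B")
        return res.x if np.isfinite(self(res.x)) else x0
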