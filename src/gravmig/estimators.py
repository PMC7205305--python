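"""Estimator front-ends in the scikit-learn style.

:class:`GravityMigrationModel` fits the cross-scale gravity model — fine
pair design, population-weighted aggregation, binomial likelihood at the
coarse level, Cauchy priors, multi-chain adaptive Metropolis — and exposes
posterior summaries and prediction of proportions and flows at any level.
:class:`ForwardDICSelector` wraps it in forward stepwise covariate
selection by DIC.  Both follow the fit/predict, ``get_params``/
``set_params`` conventions and store fitted state in trailing-underscore
attributes.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .covariates import BASE_GRAVITY, ModelSpec, build_pair_design
from .flows import aggregate_flows, flows_from_proportions
from .inference import (McmcSettings, dic, dispersed_inits, gelman_rubin,
                        posterior_summary, run_multichain)
from .landscape import pairwise_distances, validate_unit_table
from .model import (CoarseFlows, CrossScalePosterior, PriorSpec,
                    aggregate_proportions, predict_vij, proportion_matrix)
from .selection import forward_select


def _spec_seed(master: int, covariates: tuple[str, ...]) -> int:
    """Deterministic per-specification child seed below 2**31."""
    tag = zlib.crc32(",".join(covariates).encode())
    return int((master * 1_000_003 + tag) % (2**31 - 1))


class GravityMigrationModel(BaseEstimator):
    """Bayesian gravity model fitted across administrative scales.

    Fits logit(v_ij) = beta0 + beta·x_ij on all ordered fine-unit pairs to
    migrant counts observed only for coarse-unit pairs, by aggregating the
    fine proportions with population weights inside a binomial likelihood.
    The broad-scale (single level) model is the degenerate case where each
    coarse unit holds one fine unit.

    Parameters
    ----------
    covariates : tuple of str
        Covariate names in design order; the intercept is implicit.
    slope_scale, intercept_scale : float
        Cauchy prior scales.
    n_chains, n_steps, burn_in_fraction, thin : MCMC protocol
        Defaults follow the full protocol (5 × 150 000 steps, half burn-in,
        thin 10); reduce for exploratory fits.
    seed : int
        Master seed; chain seeds and dispersed initial values derive from it.

    Attributes
    ----------
    design_ : PairDesign        standardized ordered-pair design
    scalers_ : dict             fitted covariate transforms
    sample_ : PosteriorSample   retained multi-chain draws
    summary_ : DataFrame        median, 95% CI and R-hat per parameter
    coef_ : ndarray             posterior-median slopes (design order)
    intercept_ : float          posterior-median intercept
    dic_, p_d_ : float          DIC and effective parameter count
    rhat_ : ndarray             Gelman–Rubin PSRF per parameter
    """

    def __init__(self, covariates: tuple[str, ...] = BASE_GRAVITY,
                 slope_scale: float = 2.5, intercept_scale: float = 10.0,
                 n_chains: int = 5, n_steps: int = 150_000,
                 burn_in_fraction: float = 0.5, thin: int = 10,
                 init_proposal_scale: float = 0.1,
                 init_dispersion: float = 0.25, seed: int = 0):
        self.covariates = covariates
        self.slope_scale = slope_scale
        self.intercept_scale = intercept_scale
        self.n_chains = n_chains
        self.n_steps = n_steps
        self.burn_in_fraction = burn_in_fraction
        self.thin = thin
        self.init_proposal_scale = init_proposal_scale
        self.init_dispersion = init_dispersion
        self.seed = seed

    # -- fitting -----------------------------------------------------------

    def fit(self, units: pd.DataFrame, flows: CoarseFlows, adjacency=None,
            distances: pd.DataFrame | None = None, partition=None):
        """Fit to coarse flow counts observed over ``partition`` groups.

        ``partition`` maps fine ids to the groups at which ``flows`` were
        observed; by default the unit table's ``coarse_id``.  Distances are
        computed from centroids when not supplied.
        """
        units = validate_unit_table(units)
        if distances is None:
            distances = pairwise_distances(units)
        spec = ModelSpec(tuple(self.covariates))
        design, scalers = build_pair_design(units, adjacency, distances, spec)
        priors = PriorSpec(self.slope_scale, self.intercept_scale)
        posterior = CrossScalePosterior(design, units, flows,
                                        partition=partition, priors=priors)
        settings = McmcSettings(
            n_chains=self.n_chains, n_steps=self.n_steps,
            burn_in_fraction=self.burn_in_fraction, thin=self.thin,
            init_proposal_scale=self.init_proposal_scale,
            seed=_spec_seed(self.seed, spec.covariates))
        # chains start from prior-truncated jitter around the posterior mode:
        # dispersed enough for R-hat to detect non-mixing, close enough that
        # random-walk chains reach stationarity within practical burn-ins
        inits = dispersed_inits(settings.n_chains, spec.n_params, priors,
                                seed=settings.seed, logpost=posterior,
                                center=posterior.map_estimate(),
                                dispersion=self.init_dispersion)
        sample = run_multichain(posterior, inits, settings,
                                loglik=posterior.loglik,
                                param_names=spec.param_names)
        self.units_ = units
        self.spec_ = spec
        self.priors_ = priors
        self.design_ = design
        self.scalers_ = scalers
        self.posterior_ = posterior
        self.sample_ = sample
        self.summary_ = posterior_summary(sample)
        medians = self.summary_["median"].to_numpy()
        self.intercept_ = float(medians[0])
        self.coef_ = medians[1:]
        self.dic_, self.p_d_ = dic(sample)
        self.rhat_ = gelman_rubin(sample)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "sample_"):
            raise NotFittedError("fit the model before predicting")

    @property
    def beta_(self) -> np.ndarray:
        """Posterior-median coefficient vector (intercept first)."""
        self._check_fitted()
        return np.concatenate([[self.intercept_], self.coef_])

    # -- prediction --------------------------------------------------------

    def predict_proportions(self, units: pd.DataFrame | None = None,
                            adjacency=None, distances=None) -> pd.DataFrame:
        """Fine origin × destination proportion matrix at the posterior
        median, reusing the stored covariate transforms for new units."""
        self._check_fitted()
        if units is None:
            design = self.design_
        else:
            units = validate_unit_table(units)
            if distances is None:
                distances = pairwise_distances(units)
            design, _ = build_pair_design(units, adjacency, distances,
                                          self.spec_, scalers=self.scalers_)
        return proportion_matrix(design, predict_vij(self.beta_, design))

    def predict_coarse_proportions(self, partition=None) -> pd.DataFrame:
        """Aggregated group-pair proportions P_IJ at the posterior median."""
        self._check_fitted()
        v = self.predict_proportions()
        return aggregate_proportions(v, self.units_, partition)

    def predict_flows(self, sampling_fraction: float = 1.0,
                      partition=None) -> pd.DataFrame:
        """Expected person flows at the fitted units, optionally aggregated
        to ``partition`` groups."""
        self._check_fitted()
        f = flows_from_proportions(self.predict_proportions(), self.units_,
                                   sampling_fraction)
        if partition is not None:
            f = aggregate_flows(f, partition)
        return f


class ForwardDICSelector(BaseEstimator):
    """Forward stepwise covariate selection by DIC.

    Starts from the base gravity specification and adds, one per iteration,
    the candidate covariate that lowers the DIC most, while the improvement
    exceeds ``stop_threshold``.  Search fits may use shortened chains
    (``n_steps``); the selected model is refit at ``refit_n_steps`` ×
    ``refit_n_chains`` when those are given.

    Attributes: ``trace_`` (SelectionTrace), ``best_covariates_``,
    ``best_model_`` (a fitted :class:`GravityMigrationModel`).
    """

    def __init__(self, candidates: tuple[str, ...],
                 base_covariates: tuple[str, ...] = BASE_GRAVITY,
                 stop_threshold: float = 2.0,
                 n_chains: int = 3, n_steps: int = 6000,
                 burn_in_fraction: float = 0.5, thin: int = 5,
                 refit_n_chains: int | None = None,
                 refit_n_steps: int | None = None,
                 slope_scale: float = 2.5, intercept_scale: float = 10.0,
                 seed: int = 0):
        self.candidates = candidates
        self.base_covariates = base_covariates
        self.stop_threshold = stop_threshold
        self.n_chains = n_chains
        self.n_steps = n_steps
        self.burn_in_fraction = burn_in_fraction
        self.thin = thin
        self.refit_n_chains = refit_n_chains
        self.refit_n_steps = refit_n_steps
        self.slope_scale = slope_scale
        self.intercept_scale = intercept_scale
        self.seed = seed

    def _make_model(self, covariates, n_chains, n_steps) -> GravityMigrationModel:
        return GravityMigrationModel(
            covariates=covariates, slope_scale=self.slope_scale,
            intercept_scale=self.intercept_scale, n_chains=n_chains,
            n_steps=n_steps, burn_in_fraction=self.burn_in_fraction,
            thin=self.thin, seed=self.seed)

    def fit(self, units: pd.DataFrame, flows: CoarseFlows, adjacency=None,
            distances: pd.DataFrame | None = None, partition=None):
        units = validate_unit_table(units)
        if distances is None:
            distances = pairwise_distances(units)

        def fit_spec(spec: ModelSpec) -> GravityMigrationModel:
            model = self._make_model(spec.covariates, self.n_chains, self.n_steps)
            return model.fit(units, flows, adjacency=adjacency,
                             distances=distances, partition=partition)

        trace = forward_select(ModelSpec(tuple(self.base_covariates)),
                               list(self.candidates), fit_spec,
                               stop_threshold=self.stop_threshold)
        self.trace_ = trace
        self.best_covariates_ = tuple(trace.best["covariates"])
        final = self._make_model(self.best_covariates_,
                                 self.refit_n_chains or self.n_chains,
                                 self.refit_n_steps or self.n_steps)
        self.best_model_ = final.fit(units, flows, adjacency=adjacency,
                                     distances=distances, partition=partition)
        return self

    @property
    def trace_frame_(self) -> pd.DataFrame:
        if not hasattr(self, "trace_"):
            raise NotFittedError("fit the selector first")
        return self.trace_.to_frame()
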