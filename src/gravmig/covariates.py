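"""Covariate construction and standardization for the pairwise design.

Continuous covariates are scaled to mean 0 and standard deviation 0.5 and
binary covariates centred to mean 0 with range 1, the Gelman rescaling that
puts logistic-regression coefficients on comparable footing.  Standardization
is fitted on the pair-level design rows (where the regression sees the data),
and each fitted transform is recorded in a :class:`Scaler` so that it can be
re-applied bit-identically at prediction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .landscape import Adjacency, validate_unit_table

#: covariate vocabulary; order here is cosmetic, ModelSpec order governs the design
COVARIATES = (
    "DIST_ij",
    "POP_i", "POP_j",
    "GECON_i", "GECON_j",
    "TINY_i", "TINY_j",
    "URBANPROP_i", "URBANPROP_j",
    "PERC_i", "PERC_j",
    "MAJCEN_i", "MAJCEN_j",
    "CONT_ij",
)

BINARY_COVARIATES = frozenset({"TINY_i", "TINY_j", "MAJCEN_i", "MAJCEN_j", "CONT_ij"})

#: unit-level attribute feeding each *_i / *_j covariate
_UNIT_SOURCES = {
    "POP": "population",
    "GECON": "gcp_pc",
    "URBANPROP": "urban_prop",
    "PERC": "PERC",
    "TINY": "TINY",
    "MAJCEN": "MAJCEN",
}

BASE_GRAVITY = ("DIST_ij", "POP_j", "POP_i")


@dataclass(frozen=True)
class ModelSpec:
    """Ordered covariate set; the intercept is always implicit."""

    covariates: tuple[str, ...] = BASE_GRAVITY

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        unknown = [c for c in self.covariates if c not in COVARIATES]
        if unknown:
            raise ValueError(f"unknown covariates: {unknown}")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariates")

    @property
    def n_params(self) -> int:
        """Number of regression parameters including the intercept."""
        return len(self.covariates) + 1

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("Intercept",) + self.covariates

    def with_added(self, name: str) -> "ModelSpec":
        return ModelSpec(self.covariates + (name,))


@dataclass(frozen=True)
class Scaler:
    """Recorded standardization transform for one covariate.

    ``continuous``: x -> (x - center) / scale with scale = 2 * sample sd.
    ``binary``:     x -> x - center with scale fixed at 1.
    """

    kind: str
    center: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in {"continuous", "binary"}:
            raise ValueError(f"unknown scaler kind {self.kind!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, values) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.center) / self.scale


def standardize_continuous(values) -> tuple[np.ndarray, Scaler]:
    """Scale to mean 0, sample sd 0.5 (division by twice the sd)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    scaler = Scaler("continuous", center=float(x.mean()), scale=float(2.0 * sd))
    return scaler.apply(x), scaler


def center_binary(values) -> tuple[np.ndarray, Scaler]:
    """Centre a 0/1 indicator to mean 0; the range stays exactly 1."""
    x = np.asarray(values, dtype=float)
    if not np.isin(x, [0.0, 1.0]).all():
        raise ValueError("binary covariate must contain only 0 and 1")
    if np.unique(x).size < 2:
        raise ValueError("binary covariate has a single level")
    scaler = Scaler("binary", center=float(x.mean()), scale=1.0)
    return scaler.apply(x), scaler


def percentile_features(populations) -> pd.DataFrame:
    """Population percentile and the tiny / major-centre indicators.

    PERC is the empirical percentile in [0, 1] (average ranks mapped to
    [0, 1]); TINY flags populations strictly below the 10th-percentile value
    and MAJCEN those strictly above the 90th, thresholds taken with the
    linear-interpolation percentile.
    """
    pop = np.asarray(populations, dtype=float)
    if pop.size < 2:
        raise ValueError("need at least two populations")
    if (pop <= 0).any():
        raise ValueError("populations must be positive")
    ranks = rankdata(pop, method="average")
    perc = (ranks - 1.0) / (pop.size - 1.0)
    p10 = np.percentile(pop, 10)
    p90 = np.percentile(pop, 90)
    return pd.DataFrame({
        "PERC": perc,
        "TINY": (pop < p10).astype(int),
        "MAJCEN": (pop > p90).astype(int),
    })


class PairDesign:
    """All ordered origin–destination pairs with standardized covariates.

    ``frame`` has one row per ordered pair (i, j), i ≠ j, carrying the fine
    and coarse ids, the origin's raw population ``N_i`` and the standardized
    covariate columns in :class:`ModelSpec` order.
    """

    def __init__(self, frame: pd.DataFrame, spec: ModelSpec, scalers: dict[str, Scaler]):
        self.frame = frame.reset_index(drop=True)
        self.spec = spec
        self.scalers = dict(scalers)

    def __len__(self) -> int:
        return len(self.frame)

    def matrix(self) -> np.ndarray:
        """Design matrix with a leading column of ones for the intercept."""
        X = self.frame[list(self.spec.covariates)].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(X)), X])

    def to_csv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            self.frame.to_csv(fh, index=False)


def _raw_pair_columns(units: pd.DataFrame, adj: Adjacency | None,
                      dist: pd.DataFrame | None, spec: ModelSpec) -> pd.DataFrame:
    units = units.reset_index(drop=True)
    feats = percentile_features(units["population"].to_numpy())
    unit_attrs = units.assign(PERC=feats["PERC"].to_numpy(),
                              TINY=feats["TINY"].to_numpy(),
                              MAJCEN=feats["MAJCEN"].to_numpy())
    n = len(units)
    oi, dj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    keep = oi.ravel() != dj.ravel()
    oi, dj = oi.ravel()[keep], dj.ravel()[keep]
    ids = units["id"].to_numpy()
    out = pd.DataFrame({
        "origin": ids[oi],
        "dest": ids[dj],
        "coarse_origin": units["coarse_id"].to_numpy()[oi],
        "coarse_dest": units["coarse_id"].to_numpy()[dj],
        "N_i": units["population"].to_numpy()[oi],
    })
    for name in spec.covariates:
        if name == "DIST_ij":
            if dist is None:
                raise ValueError("DIST_ij requested but no distance matrix supplied")
            d = dist.loc[ids, ids].to_numpy(dtype=float)
            out[name] = d[oi, dj]
        elif name == "CONT_ij":
            if adj is None:
                raise ValueError("CONT_ij requested but no adjacency supplied")
            a = pd.DataFrame(adj.matrix, index=adj.ids, columns=adj.ids)
            out[name] = a.loc[ids, ids].to_numpy()[oi, dj]
        else:
            base, side = name.rsplit("_", 1)
            source = _UNIT_SOURCES.get(base)
            if source is None or source not in unit_attrs.columns:
                raise ValueError(f"cannot compute covariate {name}")
            col = unit_attrs[source].to_numpy(dtype=float)
            out[name] = col[oi] if side == "i" else col[dj]
    return out


def build_pair_design(units: pd.DataFrame, adj: Adjacency | None,
                      dist: pd.DataFrame | None, spec: ModelSpec,
                      scalers: dict[str, Scaler] | None = None,
                      ) -> tuple[PairDesign, dict[str, Scaler]]:
    """Assemble the ordered-pair design with standardized covariate columns.

    When ``scalers`` is given (prediction on new data) the stored transforms
    are re-applied; otherwise transforms are fitted on these design rows.
    """
    validate_unit_table(units)
    raw = _raw_pair_columns(units, adj, dist, spec)
    fitted: dict[str, Scaler] = {}
    for name in spec.covariates:
        if scalers is not None:
            raw[name] = scalers[name].apply(raw[name].to_numpy())
            fitted[name] = scalers[name]
        elif name in BINARY_COVARIATES:
            raw[name], fitted[name] = center_binary(raw[name].to_numpy())
        else:
            raw[name], fitted[name] = standardize_continuous(raw[name].to_numpy())
    return PairDesign(raw, spec, fitted), fitted


def save_scalers(scalers: dict[str, Scaler], path: str | Path) -> None:
    payload = {k: {"kind": s.kind, "center": s.center, "scale": s.scale}
               for k, s in scalers.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_scalers(path: str | Path) -> dict[str, Scaler]:
    payload = json.loads(Path(path).read_text())
    return {k: Scaler(**v) for k, v in payload.items()}
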