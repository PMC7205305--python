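"""Forward stepwise covariate selection by DIC.

Starting from the basic gravity specification (distance plus the two
populations), each remaining candidate covariate is fitted added-singly and
the one giving the lowest DIC is adopted, provided it improves the incumbent
DIC by more than a stop threshold (default 2, the conventional "substantial"
DIC difference).  The full trace — one row per adopted iteration — mirrors
the shape of an iterative selection table (iteration, covariate added,
covariate set, DIC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .covariates import ModelSpec

logger = logging.getLogger(__name__)


@dataclass
class SelectionTrace:
    """Ordered record of the forward-selection path."""

    entries: list[dict]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty selection trace")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def best(self) -> dict:
        return self.entries[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "iteration": e["iteration"],
                "added": e["added"],
                "explanatory_variables": ", ".join(e["covariates"]),
                "dic": e["dic"],
            }
            for e in self.entries
        ])

    def to_csv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            self.to_frame().to_csv(fh, index=False)


def forward_select(base: ModelSpec, candidates, fit, stop_threshold: float = 2.0,
                   ) -> SelectionTrace:
    """Greedy forward selection over ``candidates`` by lowest DIC.

    ``fit`` maps a :class:`ModelSpec` to an object with a ``dic_`` (or
    ``dic``) attribute, or to a plain (sample, dic) tuple.  A candidate whose fit raises is
    skipped with a warning; if every candidate of an iteration fails, an
    error is raised.  Exact DIC ties are broken by candidate order.
    """
    candidates = list(candidates)
    if set(candidates) & set(base.covariates):
        raise ValueError("candidates overlap the base specification")

    def _dic_of(fitted) -> float:
        if isinstance(fitted, tuple):
            return float(fitted[1])
        for attr in ("dic_", "dic"):
            if hasattr(fitted, attr):
                return float(getattr(fitted, attr))
        raise TypeError("fit result carries no DIC")

    incumbent = base
    incumbent_dic = _dic_of(fit(base))
    entries = [{
        "iteration": 1, "added": "", "covariates": list(base.covariates),
        "dic": incumbent_dic,
    }]
    iteration = 1
    while candidates:
        results: list[tuple[float, str]] = []
        n_failed = 0
        for name in candidates:
            try:
                results.append((_dic_of(fit(incumbent.with_added(name))), name))
            except Exception as exc:  # noqa: BLE001 - candidate failures are survivable
                n_failed += 1
                logger.warning("candidate %s failed to fit: %s", name, exc)
        if not results:
            raise RuntimeError("all candidate fits failed")
        best_dic, best_name = min(results, key=lambda t: (t[0], candidates.index(t[1])))
        if incumbent_dic - best_dic <= stop_threshold:
            break
        incumbent = incumbent.with_added(best_name)
        incumbent_dic = best_dic
        candidates.remove(best_name)
        iteration += 1
        entries.append({
            "iteration": iteration, "added": best_name,
            "covariates": list(incumbent.covariates), "dic": best_dic,
        })
    return SelectionTrace(entries)
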