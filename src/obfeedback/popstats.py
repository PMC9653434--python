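"""Population-vector statistics: odor-separation distances and the
linear-subtraction characterisation of light effects.

Population vectors collect, per session, the averaged z-score responses of
odor-responsive cells to one odor condition. The separation between two such
vectors p and q is the Euclidean distance d(p, q) = sqrt((p-q)·(p-q)'). In
the "between odors" design the two vectors are the responses to the two odors
presented that day (cells responsive to both odors); in the "within odor"
design they are two half-splits of the same odor's trials (cells responsive
to that odor). Sessions enter the analysis only if at least 5 cells qualify.

The linear-subtraction analysis regresses each cell-odor pair's response
under simultaneous odor + light stimulation on its odor-only response: a
slope of 1 with a negative intercept — and no correlation between the light
effect and the odor-response magnitude — is the signature of a uniform
subtractive shift of the population response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidParameterError, PairingError

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationVector",
    "DistanceResult",
    "SubtractionFit",
    "euclidean_distance",
    "build_population_vectors",
    "distance_analysis",
    "compare_conditions",
    "linear_subtraction_fit",
]


@dataclass(frozen=True)
class PopulationVector:
    """Ordered per-cell averaged responses for one odor condition."""

    values: np.ndarray
    cells: tuple
    session: str
    odor: str
    condition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "cells", tuple(self.cells))
        if self.values.ndim != 1 or self.values.size != len(self.cells):
            raise InvalidParameterError(
                f"vector of {self.values.size} values for {len(self.cells)} cells"
            )


@dataclass
class DistanceResult:
    """Per-session distances for one design, with exclusion bookkeeping."""

    design: str
    distances: pd.DataFrame          # columns: session, odor, condition, distance
    exclusions: list[dict]


@dataclass
class SubtractionFit:
    """OLS fit of odor+light responses on odor-only responses."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    difference_correlation: float
    difference_correlation_p: float
    n: int


def euclidean_distance(p: PopulationVector, q: PopulationVector) -> float:
    """d(p, q) = sqrt((p - q)·(p - q)') over matched cell orderings."""
    if p.cells != q.cells:
        raise PairingError(
            f"population vectors have mismatched cells: {p.cells} vs {q.cells}"
        )
    diff = p.values - q.values
    return float(np.sqrt(np.dot(diff, diff)))


def _split_halves(
    trials: np.ndarray, strategy: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split trial indices into two halves (odd/even order, or random)."""
    order = np.sort(trials)
    if strategy == "half":
        return order[0::2], order[1::2]
    if strategy == "random":
        perm = rng.permutation(order)
        mid = perm.size // 2
        return perm[:mid], perm[mid:]
    raise InvalidParameterError(f"unknown split strategy {strategy!r}")


def build_population_vectors(
    trial_responses: pd.DataFrame,
    responsiveness: pd.DataFrame,
    design: str,
    min_cells: int = 5,
    split: str = "half",
    seed: int = 0,
) -> tuple[list[dict], list[dict]]:
    """Construct paired population vectors per session and condition.

    Parameters
    ----------
    trial_responses : DataFrame
        Tidy per-trial responses with columns
        ``session, cell, odor, condition, trial, value`` (``value`` is the
        per-trial response magnitude; vectors average it over trials).
    responsiveness : DataFrame
        Columns ``session, cell, odor, responsive`` — the α = 0.05 paired-test
        odor-responsiveness labels computed on all odor trials.
    design : {"between", "within"}
        "between": one vector per odor, over cells responsive to *both*
        odors of the pair. "within": two half-split vectors for the same
        odor, over cells responsive to that odor.
    min_cells : int
        Sessions (odor pairs / odors) with fewer qualifying cells are excluded.
    split : {"half", "random"}
        Trial-split strategy for the within design (odd/even trial order, or a
        seeded random partition).

    Returns
    -------
    (pairs, exclusions)
        ``pairs`` is a list of dicts with keys ``session, odor, condition,
        p, q`` (PopulationVectors); ``exclusions`` records sessions that
        failed the cell-count rule, with the count and reason.
    """
    if design not in ("between", "within"):
        raise InvalidParameterError(f"design must be 'between' or 'within', got {design!r}")
    rng = np.random.default_rng(seed)
    pairs: list[dict] = []
    exclusions: list[dict] = []
    resp_lookup = responsiveness.set_index(["session", "cell", "odor"])["responsive"]

    for session, sdf in trial_responses.groupby("session"):
        odors = sorted(sdf["odor"].unique())
        conditions = sorted(sdf["condition"].unique())
        if design == "between":
            for odor_a, odor_b in combinations(odors, 2):
                cells = sorted(sdf["cell"].unique())
                dual = [
                    c
                    for c in cells
                    if resp_lookup.get((session, c, odor_a), False)
                    and resp_lookup.get((session, c, odor_b), False)
                ]
                if len(dual) < min_cells:
                    exclusions.append(
                        {
                            "session": session,
                            "odor": f"{odor_a}|{odor_b}",
                            "n_cells": len(dual),
                            "reason": f"fewer than {min_cells} dual-responsive cells",
                        }
                    )
                    continue
                for cond in conditions:
                    vecs = {}
                    for odor in (odor_a, odor_b):
                        sub = sdf[(sdf["odor"] == odor) & (sdf["condition"] == cond)]
                        means = sub.groupby("cell")["value"].mean()
                        vecs[odor] = PopulationVector(
                            values=means.reindex(dual).to_numpy(),
                            cells=dual,
                            session=str(session),
                            odor=str(odor),
                            condition=str(cond),
                        )
                    pairs.append(
                        {
                            "session": session,
                            "odor": f"{odor_a}|{odor_b}",
                            "condition": cond,
                            "p": vecs[odor_a],
                            "q": vecs[odor_b],
                        }
                    )
        else:  # within
            for odor in odors:
                cells = sorted(sdf["cell"].unique())
                responsive = [
                    c for c in cells if resp_lookup.get((session, c, odor), False)
                ]
                if len(responsive) < min_cells:
                    exclusions.append(
                        {
                            "session": session,
                            "odor": odor,
                            "n_cells": len(responsive),
                            "reason": f"fewer than {min_cells} responsive cells",
                        }
                    )
                    continue
                for cond in conditions:
                    sub = sdf[(sdf["odor"] == odor) & (sdf["condition"] == cond)]
                    trials = np.unique(sub["trial"].to_numpy())
                    half_a, half_b = _split_halves(trials, split, rng)
                    halves = []
                    for half in (half_a, half_b):
                        hsub = sub[sub["trial"].isin(half)]
                        means = hsub.groupby("cell")["value"].mean()
                        halves.append(
                            PopulationVector(
                                values=means.reindex(responsive).to_numpy(),
                                cells=responsive,
                                session=str(session),
                                odor=str(odor),
                                condition=str(cond),
                            )
                        )
                    pairs.append(
                        {
                            "session": session,
                            "odor": odor,
                            "condition": cond,
                            "p": halves[0],
                            "q": halves[1],
                        }
                    )
    if not pairs:
        logger.warning(
            "build_population_vectors: no session qualified (design=%s, min_cells=%d)",
            design, min_cells,
        )
    return pairs, exclusions


def distance_analysis(
    pairs: list[dict], exclusions: list[dict] | None = None, design: str = "between"
) -> DistanceResult:
    """Euclidean distances for every vector pair, tabulated per session/condition.

    No statistical verdict is embedded: the paired comparison across sessions
    is applied downstream (see :func:`compare_conditions`) and reported with
    the distances.
    """
    rows = []
    for pair in pairs:
        rows.append(
            {
                "session": pair["session"],
                "odor": pair["odor"],
                "condition": pair["condition"],
                "distance": euclidean_distance(pair["p"], pair["q"]),
            }
        )
    df = pd.DataFrame(rows, columns=["session", "odor", "condition", "distance"])
    return DistanceResult(design=design, distances=df, exclusions=exclusions or [])


def compare_conditions(
    result: DistanceResult, condition_a: str, condition_b: str
) -> tuple[pd.DataFrame, float]:
    """Pair per-session distances across two conditions and t-test them.

    Sessions (session × odor pairs) lacking either condition are dropped with
    a log message. Returns the paired table and the two-sided paired-t p-value
    (NaN when fewer than 2 pairs remain).
    """
    df = result.distances
    wide = df.pivot_table(
        index=["session", "odor"], columns="condition", values="distance"
    )
    for cond in (condition_a, condition_b):
        if cond not in wide.columns:
            logger.warning("compare_conditions: condition %r absent", cond)
            return pd.DataFrame(), np.nan
    paired = wide[[condition_a, condition_b]].dropna()
    dropped = len(wide) - len(paired)
    if dropped:
        logger.info("compare_conditions: dropped %d unpaired session(s)", dropped)
    # prefix the value columns so a condition named like an index level
    # ("odor") cannot collide on reset_index
    a = paired[condition_a].to_numpy()
    b = paired[condition_b].to_numpy()
    paired = paired.rename(
        columns={condition_a: f"distance_{condition_a}",
                 condition_b: f"distance_{condition_b}"}
    ).reset_index()
    if len(paired) < 2:
        return paired, np.nan
    if np.allclose(a, b):
        return paired, 1.0
    return paired, float(stats.ttest_rel(a, b).pvalue)


def linear_subtraction_fit(
    odor_responses: np.ndarray, odor_light_responses: np.ndarray
) -> SubtractionFit:
    """OLS fit of odor+light vs odor-only responses over responsive pairs.

    Reports slope/intercept with 95% confidence intervals and the Pearson
    correlation between the light effect (odor+light − odor) and the
    odor-response magnitude. A pure subtractive effect gives slope 1,
    intercept −c and zero difference correlation; a divisive effect gives a
    slope below 1.
    """
    x = np.asarray(odor_responses, dtype=float)
    y = np.asarray(odor_light_responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PairingError(f"mismatched response vectors: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise InvalidParameterError(f"need at least 3 matched pairs, got {x.size}")
    if np.allclose(x.std(), 0.0):
        raise InvalidParameterError("degenerate odor responses (zero variance)")
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    ci = ols.conf_int(alpha=0.05)
    diff = y - x
    if np.allclose(diff.std(), 0.0):
        corr, corr_p = 0.0, 1.0
    else:
        corr, corr_p = stats.pearsonr(diff, x)
    return SubtractionFit(
        slope=float(ols.params[1]),
        intercept=float(ols.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        difference_correlation=float(corr),
        difference_correlation_p=float(corr_p),
        n=int(x.size),
    )
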