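"""Selection-coefficient estimation from competition assays.

Endpoint mode uses count ratios of an unlabeled strain U against a
fluorescent reference R: s = (ln(U_f/R_f) - ln(U_i/R_i)) / T, with relative
fitness reported as 1 + s; counts may first be corrected for the fraction of
labeled-but-non-fluorescent cells and the marker's own expression cost.
Slope mode fits ln(background-corrected mutant/reference fluorescence)
against generations, pools dye-swapped orientations and subtracts the
parental-vs-parental control slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "CompetitionRecord", "FluorescenceSeries", "SelectionEstimate",
    "endpoint_selection", "correct_counts", "slope_fitness",
    "concentration_response", "series_log_ratio",
]


@dataclass(frozen=True)
class CompetitionRecord:
    """Endpoint counts of unlabeled (U) vs fluorescent reference (R) strains
    over T generations of reference proliferation."""
    U_i: float
    U_f: float
    R_i: float
    R_f: float
    T: float
    replicate: str = ""

    def __post_init__(self) -> None:
        if min(self.U_i, self.U_f, self.R_i, self.R_f) <= 0:
            raise ValueError(
                "counts must be > 0; if a strain was not detected, add "
                "pseudo-counts explicitly before constructing the record")
        if self.T <= 0:
            raise ValueError("T must be > 0")


@dataclass(frozen=True)
class FluorescenceSeries:
    """One two-colour competition time course."""
    generations: np.ndarray
    channel1: np.ndarray
    channel2: np.ndarray
    background1: float
    background2: float
    orientation: str = "mutant-in-channel-1"   # or "mutant-in-channel-2"
    replicate: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.generations, dtype=float)
        if len(g) < 2:
            raise ValueError("need at least 2 time points")
        if (np.diff(g) < 0).any():
            raise ValueError("generations must be non-decreasing")
        if (np.asarray(self.channel1) <= self.background1).any() or \
           (np.asarray(self.channel2) <= self.background2).any():
            raise ValueError("signals must exceed background")


@dataclass
class SelectionEstimate:
    s: float
    se: float
    n_replicates: int
    dye_swapped: bool = True
    notes: str = ""

    @property
    def fitness(self) -> float:
        return 1.0 + self.s


def endpoint_selection(record: CompetitionRecord) -> float:
    """s = (ln(U_f/R_f) - ln(U_i/R_i)) / T."""
    return (math.log(record.U_f / record.R_f)
            - math.log(record.U_i / record.R_i)) / record.T


def correct_counts(record: CompetitionRecord, phi: float = 0.0,
                   marker_cost: float = 0.0) -> tuple[CompetitionRecord, float]:
    """Correct for non-fluorescent labeled cells and the marker's cost.

    A fraction ``phi`` of reference cells does not fluoresce and is scored
    as unlabeled: true reference counts are R/(1-phi), and the miscounted
    cells R*phi/(1-phi) are removed from the unlabeled pool. ``marker_cost``
    (s_m >= 0 when the marker burdens the reference) is added to the raw s.
    Returns ``(corrected record, adjusted s)``.
    """
    if not 0 <= phi < 1:
        raise ValueError("phi must be in [0, 1)")
    if phi > 0:
        vals = {}
        for u_name, r_name in (("U_i", "R_i"), ("U_f", "R_f")):
            r_obs = getattr(record, r_name)
            u_obs = getattr(record, u_name)
            r_corr = r_obs / (1 - phi)
            u_corr = u_obs - r_obs * phi / (1 - phi)
            if u_corr <= 0:
                raise ValueError(f"correction drives {u_name} non-positive")
            vals[u_name], vals[r_name] = u_corr, r_corr
        record = replace(record, **vals)
    return record, endpoint_selection(record) + marker_cost


def series_log_ratio(series: FluorescenceSeries) -> np.ndarray:
    """ln of background-corrected channel-1 over channel-2 signal."""
    return np.log((np.asarray(series.channel1, dtype=float) - series.background1)
                  / (np.asarray(series.channel2, dtype=float) - series.background2))


def _robust_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Bisquare-weighted robust slope; ordinary least squares below 4 points."""
    if len(x) < 4:
        return float(np.polyfit(x, y, 1)[0])
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning
    X = sm.add_constant(x)
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        # a perfect (noiseless) fit drives the robust scale to zero
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit()
    return float(fit.params[1])


def slope_fitness(series_list: list[FluorescenceSeries],
                  control: list[FluorescenceSeries] | None = None
                  ) -> SelectionEstimate:
    """Pool per-replicate slopes of ln(mutant/reference) vs generations.

    Series in the swapped orientation (mutant carrying the channel-2
    fluorophore) have their raw slopes negated before pooling; the mean
    slope of the parental-vs-parental control series is subtracted.
    """
    if not series_list:
        raise ValueError("no series given")
    slopes = []
    orientations = set()
    for s in series_list:
        raw = _robust_slope(np.asarray(s.generations, dtype=float),
                            series_log_ratio(s))
        if s.orientation == "mutant-in-channel-2":
            raw = -raw
        orientations.add(s.orientation)
        slopes.append(raw)
    control_slope = 0.0
    if control:
        control_slope = float(np.mean(
            [_robust_slope(np.asarray(c.generations, dtype=float),
                           series_log_ratio(c)) for c in control]))
    slopes = np.asarray(slopes) - control_slope
    swapped = len(orientations) > 1
    return SelectionEstimate(
        s=float(slopes.mean()),
        se=float(slopes.std(ddof=1) / np.sqrt(len(slopes))) if len(slopes) > 1 else 0.0,
        n_replicates=len(slopes), dye_swapped=swapped,
        notes="" if swapped else "no dye-swap: single orientation only")


def concentration_response(estimates_by_condition: dict[str, list[float]],
                           reference: str = "0%") -> dict:
    """One-way ANOVA of replicate selection coefficients across conditions,
    plus per-condition Welch contrasts against the reference condition."""
    conditions = list(estimates_by_condition)
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    groups = [np.asarray(estimates_by_condition[c], dtype=float)
              for c in conditions]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 replicates per condition")
    if max(g.var() for g in groups) == 0 and \
            len({g.mean() for g in groups}) == 1:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*groups)
    contrasts = {}
    if reference in estimates_by_condition:
        ref = np.asarray(estimates_by_condition[reference], dtype=float)
        for c in conditions:
            if c == reference:
                continue
            g = np.asarray(estimates_by_condition[c], dtype=float)
            if g.var(ddof=1) == 0 and ref.var(ddof=1) == 0:
                contrasts[c] = 1.0 if g.mean() == ref.mean() else 0.0
            else:
                contrasts[c] = float(stats.ttest_ind(g, ref, equal_var=False).pvalue)
    return {"F": float(f_stat), "p": float(p), "contrasts": contrasts}
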