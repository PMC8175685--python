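"""Downstream outcome chains, rate-table arithmetic and statistics.

After injection, each zygote runs a chain of Bernoulli trials: survive
the injection, develop to the 2-cell stage in culture (every 2-cell
embryo is transferred to a recipient), become a live offspring, and -
given an offspring - carry the genetic modification.  Arm probabilities
default to the empirical rates of the three chemistries tested with the
automated system (traditional DNA injection, piggyBac transposon,
CRISPR knock-in) alongside their manual controls.

Percentages are reported the way the source table prints them: one
decimal, rounded half-up, with the number of transferred embryos as the
denominator.  Group summaries are mean +/- standard error of the mean and
two-sided equal-variance Student t-tests with significance at P < 0.01.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "ArmConfig",
    "OutcomeRow",
    "StatsSummary",
    "TTestResult",
    "percent_round",
    "simulate_outcomes",
    "outcome_table",
    "summarize_mean_sem",
    "two_sample_t",
    "PUBLISHED_TABLE",
    "DEFAULT_ARMS",
]


def percent_round(numerator: int, denominator: int) -> float:
    """100*numerator/denominator rounded half-up to one decimal.

    Computed in exact decimal arithmetic so printed-table regression is
    bit-faithful (half-up, not banker's rounding).
    """
    if denominator <= 0:
        raise ConfigurationError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ConfigurationError("numerator must lie in [0, denominator]")
    q = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


@dataclass
class ArmConfig:
    label: str
    injection_method: str = "full_auto"  # full_auto | manual
    injection_time_s: float | None = None
    dna_conc_ng_ul: float = 2.0
    p_survival: float = 0.85
    p_2cell: float = 0.88
    p_offspring_given_transfer: float = 0.2
    p_modified_given_transfer: float = 0.02

    def __post_init__(self):
        if self.injection_method not in ("full_auto", "manual"):
            raise ConfigurationError("injection_method must be "
                                     "'full_auto' or 'manual'")
        for name in ("p_survival", "p_2cell", "p_offspring_given_transfer",
                     "p_modified_given_transfer"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")


@dataclass
class OutcomeRow:
    label: str
    injection_method: str
    injection_time_s: float | None
    dna_conc_ng_ul: float
    n_transferred: int
    n_offspring: int
    pct_offspring: float
    n_modified: int
    pct_modified: float


@dataclass
class StatsSummary:
    label: str
    mean: float
    sem: float
    n_replicates: int


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    significant: bool  # at P < 0.01


# ---------------------------------------------------------------------------
# outcome simulation


def simulate_outcomes(injected, arm: ArmConfig, rng: np.random.Generator):
    """Chained per-zygote Bernoulli outcomes for one experimental arm.

    `injected` is either a count of injected zygotes or a list of batch
    records (only entries with final_status == 'injected' enter the
    chain).  Every 2-cell embryo is transferred; modification is only
    possible given an offspring.
    """
    if isinstance(injected, int):
        n = injected
    else:
        n = sum(1 for r in injected
                if getattr(r, "final_status", "injected") == "injected")
    if n < 0:
        raise ConfigurationError("injected count must be >= 0")
    out = []
    for _ in range(n):
        survived = rng.random() < arm.p_survival
        two_cell = survived and rng.random() < arm.p_2cell
        transferred = two_cell
        offspring = transferred and rng.random() < arm.p_offspring_given_transfer
        modified = offspring and rng.random() < arm.p_modified_given_transfer
        out.append({"survived": survived, "two_cell": two_cell,
                    "transferred": transferred, "offspring": offspring,
                    "modified": modified})
    return out


def _counts_from_group(entry):
    """Accept either (transferred, offspring, modified) counts or a list of
    simulated outcome records."""
    if isinstance(entry, tuple) and len(entry) == 3:
        return tuple(int(v) for v in entry)
    n_tr = sum(1 for r in entry if r["transferred"])
    n_off = sum(1 for r in entry if r["offspring"])
    n_mod = sum(1 for r in entry if r["modified"])
    return n_tr, n_off, n_mod


def outcome_table(groups) -> pd.DataFrame:
    """One row per arm: counts and one-decimal percentages.

    `groups` is a list of (ArmConfig, records-or-(transferred, offspring,
    modified) counts).  Given printed counts as direct input the table
    reproduces printed percentages exactly.
    """
    rows = []
    for arm, entry in groups:
        n_tr, n_off, n_mod = _counts_from_group(entry)
        if not 0 <= n_mod <= n_off <= n_tr:
            raise ConfigurationError(
                f"inconsistent counts for arm {arm.label!r}: "
                f"modified {n_mod} <= offspring {n_off} <= transferred {n_tr} "
                "violated")
        rows.append(OutcomeRow(
            label=arm.label,
            injection_method=arm.injection_method,
            injection_time_s=arm.injection_time_s,
            dna_conc_ng_ul=arm.dna_conc_ng_ul,
            n_transferred=n_tr,
            n_offspring=n_off,
            pct_offspring=percent_round(n_off, n_tr) if n_tr else 0.0,
            n_modified=n_mod,
            pct_modified=percent_round(n_mod, n_tr) if n_tr else 0.0,
        ))
    return pd.DataFrame([{
        "method": r.label,
        "injection_method": r.injection_method,
        "injection_time_s": r.injection_time_s,
        "dna_conc_ng_ul": r.dna_conc_ng_ul,
        "n_transferred": r.n_transferred,
        "offspring_n": r.n_offspring,
        "offspring_pct": r.pct_offspring,
        "modified_n": r.n_modified,
        "modified_pct": r.pct_modified,
    } for r in rows])


# ---------------------------------------------------------------------------
# statistics


def summarize_mean_sem(replicate_values, label: str = "") -> StatsSummary:
    """Mean and standard error of the mean (sample sd / sqrt(n))."""
    v = np.asarray(list(replicate_values), dtype=float)
    if v.size < 2:
        raise ConfigurationError("need at least 2 replicates")
    return StatsSummary(label=label, mean=float(v.mean()),
                        sem=float(v.std(ddof=1) / np.sqrt(v.size)),
                        n_replicates=int(v.size))


def two_sample_t(a, b, alpha: float = 0.01) -> TTestResult:
    """Two-sided equal-variance Student t-test with n_a+n_b-2 df."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each group needs n >= 2")
    if a.var(ddof=1) + b.var(ddof=1) == 0.0:
        raise ConfigurationError("degenerate groups: zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    p = float(res.pvalue)
    return TTestResult(t=float(res.statistic), p=p, df=df,
                       significant=p < alpha)


# ---------------------------------------------------------------------------
# published reference inputs
#
# Printed transfer/offspring/modification counts of the three
# genetic-modification chemistries (full-auto arms injected at 30 hPa),
# used as direct inputs for table regression, plus the reported survival
# and 2-cell rates used as default simulation probabilities.

PUBLISHED_TABLE = [
    # (label, method, time_s, dna_ng_ul, transferred, offspring, modified)
    ("traditional_DI", "full_auto", 0.8, 1.5, 117, 23, 0),
    ("traditional_DI", "full_auto", 1.6, 1.5, 141, 27, 1),
    ("traditional_DI", "manual", None, 1.5, 106, 6, 2),
    ("piggyBac_TS", "full_auto", 1.6, 2.0, 110, 20, 3),
    ("piggyBac_TS", "full_auto", 1.6, 10.0, 108, 24, 9),
    ("piggyBac_TS", "manual", None, 2.0, 114, 26, 4),
    ("knock_in", "full_auto", 1.6, 2.0, 143, 37, 3),
    ("knock_in", "manual", None, 2.0, 135, 15, 2),
]


def _arm(label, method, t, conc, surv, twocell, tr, off, mod):
    return ArmConfig(
        label=label, injection_method=method, injection_time_s=t,
        dna_conc_ng_ul=conc, p_survival=surv, p_2cell=twocell,
        p_offspring_given_transfer=off / tr,
        p_modified_given_transfer=mod / tr,
    )


DEFAULT_ARMS = [
    _arm("traditional_DI", "full_auto", 0.8, 1.5, 0.874, 0.886, 117, 23, 0),
    _arm("traditional_DI", "full_auto", 1.6, 1.5, 0.794, 0.892, 141, 27, 1),
    _arm("traditional_DI", "manual", None, 1.5, 0.865, 0.828, 106, 6, 2),
    _arm("piggyBac_TS", "full_auto", 1.6, 2.0, 0.800, 0.917, 110, 20, 3),
    _arm("piggyBac_TS", "full_auto", 1.6, 10.0, 0.827, 0.871, 108, 24, 9),
    _arm("piggyBac_TS", "manual", None, 2.0, 0.827, 0.919, 114, 26, 4),
    _arm("knock_in", "full_auto", 1.6, 2.0, 0.809, 0.888, 143, 37, 3),
    _arm("knock_in", "manual", None, 2.0, 0.840, 0.804, 135, 15, 2),
]


def published_groups():
    """(ArmConfig, printed counts) pairs for table regression."""
    groups = []
    for (label, method, t, conc, tr, off, mod), arm in zip(PUBLISHED_TABLE,
                                                           DEFAULT_ARMS):
        groups.append((arm, (tr, off, mod)))
    return groups
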