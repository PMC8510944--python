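"""Cohort statistics for the blast-injury animal study.

Parses the packaged 17-animal cohort table (body weight, body-armor flag,
organ-damage remarks, immediate respiratory arrest, 3-hour outcome), builds
2x2 contingency tables, and implements the study's statistical toolkit:
two-sided Fisher exact test, survival/organ-damage summaries, a split-plot
(mixed) repeated-measures ANOVA, and the pooled-variance two-group t-test.

The Fisher test uses the probability-mass two-sided rule (sum of the
hypergeometric probabilities of all tables with the observed margins that
are no more probable than the observed table).  The repeated-measures model
is the univariate split-plot decomposition: the between-subject group
effect is tested against subject-within-group variation, the time and
group x time effects against the within-subject residual; no sphericity
correction is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ORGAN_FLAGS",
    "AnimalRecord",
    "Cohort",
    "ContingencyTable2x2",
    "packaged_cohort_path",
    "parse_cohort",
    "load_packaged_cohort",
    "tabulate",
    "fisher_exact_two_sided",
    "survival_summary",
    "repeated_measures_anova",
    "split_plot_group_f",
    "two_group_t",
]

ORGAN_FLAGS = ("LH", "hemothorax", "splenic", "liver", "IAH", "BR")

# keyword -> canonical flag; matching is case-insensitive on comma/& tokens
_KEYWORDS = {
    "lh": "LH",
    "lung hemorrhage": "LH",
    "hemothorax": "hemothorax",
    "splenic": "splenic",
    "splenic injury": "splenic",
    "liver": "liver",
    "liver injury": "liver",
    "iah": "IAH",
    "intra-abdominal hemorrhage": "IAH",
    "br": "BR",
    "bladder rupture": "BR",
}


@dataclass(frozen=True)
class AnimalRecord:
    """One animal of the cohort."""

    animal_id: int
    body_weight: float            # kg
    armor: bool
    organ_flags: frozenset = frozenset()
    respiratory_arrest: bool = False
    outcome: str = "survival"     # "survival" | "death"

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body weight must be positive")
        bad = set(self.organ_flags) - set(ORGAN_FLAGS)
        if bad:
            raise ValueError(f"unknown organ flags: {sorted(bad)}")
        if self.outcome not in ("survival", "death"):
            raise ValueError(f"outcome must be survival/death, got "
                             f"{self.outcome!r}")

    @property
    def died(self) -> bool:
        return self.outcome == "death"


@dataclass
class Cohort:
    """Ordered list of animal records with unique ids."""

    records: list = field(default_factory=list)
    unknown_remarks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.animal_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate animal ids in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, predicate) -> "Cohort":
        return Cohort(records=[r for r in self.records if predicate(r)])


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of counts with row/column labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple = ("row0", "row1")
    col_labels: tuple = ("col0", "col1")

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def margins(self) -> dict:
        m = self.array
        return {"rows": tuple(m.sum(axis=1)), "cols": tuple(m.sum(axis=0)),
                "total": int(m.sum())}


def packaged_cohort_path() -> Path:
    """Path to the packaged cohort transcription CSV."""
    return Path(resources.files("blasttube").joinpath("data/swine_cohort.csv"))


def _parse_flags(remarks: str) -> tuple[frozenset, list]:
    """Keyword-match the free-text remarks column into canonical flags."""
    flags = set()
    unknown = []
    if not isinstance(remarks, str) or not remarks.strip():
        return frozenset(), unknown
    for token in (t.strip() for part in remarks.split(",")
                  for t in part.split("&")):
        if not token:
            continue
        key = token.lower()
        matched = False
        if key in _KEYWORDS:
            flags.add(_KEYWORDS[key])
            matched = True
        else:
            for kw, flag in _KEYWORDS.items():
                if kw in key:
                    flags.add(flag)
                    matched = True
        if not matched:
            unknown.append(token)
    return frozenset(flags), unknown


_REQUIRED = ("id", "body_weight_kg", "body_armor", "organ_damage",
             "respiratory_arrest", "outcome")


def parse_cohort(path) -> Cohort:
    """Read a cohort CSV into a :class:`Cohort`.

    Required columns: id, body_weight_kg, body_armor (Yes/No), organ_damage
    (free text), respiratory_arrest (Yes/No), outcome (Survival/Death).
    Unknown remark tokens are collected on ``Cohort.unknown_remarks``.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing required columns: {missing}")
    records = []
    unknown_all = []
    for _, row in df.iterrows():
        flags, unknown = _parse_flags(row["organ_damage"])
        unknown_all.extend(unknown)
        records.append(AnimalRecord(
            animal_id=int(row["id"]),
            body_weight=float(row["body_weight_kg"]),
            armor=str(row["body_armor"]).strip().lower() in ("yes", "true", "1"),
            organ_flags=flags,
            respiratory_arrest=(str(row["respiratory_arrest"]).strip().lower()
                                in ("yes", "true", "1")),
            outcome=str(row["outcome"]).strip().lower().replace(
                "died", "death"),
        ))
    cohort = Cohort(records=records)
    cohort.unknown_remarks = unknown_all
    return cohort


def load_packaged_cohort() -> Cohort:
    """The packaged 17-animal cohort."""
    return parse_cohort(packaged_cohort_path())


def tabulate(cohort: Cohort, row_predicate, col_predicate,
             row_labels=("no", "yes"), col_labels=("no", "yes")
             ) -> ContingencyTable2x2:
    """2x2 table counting records by two boolean predicates.

    Cell layout: rows are predicate False/True, columns likewise, so
    ``a`` counts (False, False) and ``d`` counts (True, True).
    """
    counts = np.zeros((2, 2), dtype=int)
    for r in cohort:
        counts[int(bool(row_predicate(r))), int(bool(col_predicate(r)))] += 1
    return ContingencyTable2x2(a=int(counts[0, 0]), b=int(counts[0, 1]),
                               c=int(counts[1, 0]), d=int(counts[1, 1]),
                               row_labels=row_labels, col_labels=col_labels)


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float          # conditional MLE not required; sample OR
    degenerate: bool = False   # a zero row or column margin


def fisher_exact_two_sided(table: ContingencyTable2x2) -> FisherResult:
    """Two-sided Fisher exact test by the probability-mass rule.

    p is the sum of hypergeometric probabilities, over all tables with the
    observed margins, that do not exceed the observed table's probability
    (with a 1 + 1e-7 tolerance factor guarding float ties).  Degenerate
    margins (an empty row or column) give p = 1 with a flag.  The sample
    odds ratio (a d)/(b c) is reported; inf for zero cells.
    """
    m = table.array
    rows = m.sum(axis=1)
    cols = m.sum(axis=0)
    n = m.sum()
    if 0 in rows or 0 in cols:
        return FisherResult(p_value=1.0, odds_ratio=np.nan, degenerate=True)
    # hypergeometric over cell a: support
    a_obs = m[0, 0]
    a_min = max(0, rows[0] - cols[1])
    a_max = min(rows[0], cols[0])
    support = np.arange(a_min, a_max + 1)
    pmf = sps.hypergeom.pmf(support, n, rows[0], cols[0])
    p_obs = sps.hypergeom.pmf(a_obs, n, rows[0], cols[0])
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (m[0, 0] * m[1, 1]) / (m[0, 1] * m[1, 0]) \
            if m[0, 1] * m[1, 0] > 0 else np.inf
    return FisherResult(p_value=min(p, 1.0), odds_ratio=float(odds))


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class SurvivalSummary:
    n: int
    n_armor: int
    survival_fraction: dict       # group -> raw fraction
    survival_percent: dict        # group -> integer percent (half away from 0)
    organ_counts: dict            # flag -> count over the whole cohort
    n_arrest: int
    n_arrest_recovered: int
    mean_body_weight: float


def survival_summary(cohort: Cohort) -> SurvivalSummary:
    """Per-group survival proportions and organ-damage counts."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    groups = {"armor": [r for r in cohort if r.armor],
              "no_armor": [r for r in cohort if not r.armor]}
    frac = {}
    pct = {}
    for name, recs in groups.items():
        if recs:
            f = sum(not r.died for r in recs) / len(recs)
            frac[name] = f
            pct[name] = _round_half_away(100 * f)
    organ_counts = {flag: sum(flag in r.organ_flags for r in cohort)
                    for flag in ORGAN_FLAGS}
    n_arrest = sum(r.respiratory_arrest for r in cohort)
    n_rec = sum(r.respiratory_arrest and not r.died for r in cohort)
    return SurvivalSummary(
        n=len(cohort), n_armor=len(groups["armor"]),
        survival_fraction=frac, survival_percent=pct,
        organ_counts=organ_counts, n_arrest=n_arrest,
        n_arrest_recovered=n_rec,
        mean_body_weight=float(np.mean([r.body_weight for r in cohort])),
    )


# ---------------------------------------------------------------------------
# repeated-measures (split-plot) ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    f_group: float
    p_group: float
    f_time: float
    p_time: float
    f_interaction: float
    p_interaction: float
    df: dict
    excluded_subjects: tuple = ()


def repeated_measures_anova(data: pd.DataFrame, subject="subject",
                            group="group", time="time", value="value",
                            correction: str = "none") -> AnovaResult:
    """Split-plot ANOVA of a two-group repeated-measures design.

    ``data`` is long-format with subject, group, time and value columns.
    Groups may have unequal sizes; subjects must be measured at every
    timepoint — subjects with incomplete series (fewer than the full set
    of timepoints, including the < 2 case) are excluded with a warning.

    ``correction='gg'`` applies the Greenhouse-Geisser sphericity
    correction (epsilon-scaled degrees of freedom) to the within-subject
    tests; the default applies none.
    """
    df = data[[subject, group, time, value]].dropna().copy()
    times = sorted(df[time].unique())
    T = len(times)
    if T < 2:
        raise ValueError("need at least two timepoints")
    counts = df.groupby(subject)[time].nunique()
    bad = tuple(counts.index[counts < T])
    if bad:
        warnings.warn(f"excluding subjects with incomplete series: {bad}",
                      stacklevel=2)
        df = df[~df[subject].isin(bad)]
    groups_of = df.groupby(subject)[group].nunique()
    if (groups_of > 1).any():
        raise ValueError("a subject appears in more than one group")

    wide = df.pivot_table(index=[subject, group], columns=time,
                          values=value, aggfunc="mean")
    y = wide.to_numpy()                       # (N, T)
    glab = np.array([g for _, g in wide.index])
    gnames = sorted(set(glab))
    if len(gnames) != 2:
        raise ValueError("exactly two groups are required")
    labels = (glab == gnames[1]).astype(int)
    res = _split_plot(y[None, :, :], labels)
    df_out = dict(res["df"])
    p_time = float(res["p_time"][0])
    p_inter = float(res["p_inter"][0])
    if correction == "gg":
        eps = _gg_epsilon(y, labels)
        dft, dfe = df_out["time"]
        dfi, _ = df_out["interaction"]
        p_time = float(sps.f.sf(res["f_time"][0], eps * dft, eps * dfe))
        p_inter = float(sps.f.sf(res["f_inter"][0], eps * dfi, eps * dfe))
        df_out["gg_epsilon"] = eps
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return AnovaResult(
        f_group=float(res["f_group"][0]), p_group=float(res["p_group"][0]),
        f_time=float(res["f_time"][0]), p_time=p_time,
        f_interaction=float(res["f_inter"][0]),
        p_interaction=p_inter,
        df=df_out, excluded_subjects=bad)


def _gg_epsilon(y: np.ndarray, labels: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    T = y.shape[1]
    parts = []
    for g in (0, 1):
        yg = y[labels == g]
        parts.append((yg - yg.mean(axis=0)).T @ (yg - yg.mean(axis=0)))
    S = sum(parts) / (y.shape[0] - 2)
    # double-centred covariance
    Sc = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    num = np.trace(Sc) ** 2
    den = (T - 1) * np.sum(Sc * Sc)
    eps = num / den if den > 0 else 1.0
    return float(np.clip(eps, 1.0 / (T - 1), 1.0))


def _split_plot(y: np.ndarray, labels: np.ndarray) -> dict:
    """Vectorised split-plot decomposition.

    ``y`` has shape (reps, N, T); ``labels`` (N,) with values 0/1.  Returns
    F statistics and p-values per replicate.  Sums of squares follow the
    classic cell-means formulas; with unequal group sizes the group and
    cell sums are weighted by group size.
    """
    reps, N, T = y.shape
    n_g = np.array([(labels == 0).sum(), (labels == 1).sum()])
    if n_g.min() < 2:
        raise ValueError("each group needs at least two subjects")
    mu = y.mean(axis=(1, 2), keepdims=True)                   # grand
    m_s = y.mean(axis=2)                                      # (reps, N)
    m_t = y.mean(axis=1)                                      # (reps, T)
    m_g = np.stack([y[:, labels == g, :].mean(axis=(1, 2))
                    for g in (0, 1)], axis=1)                 # (reps, 2)
    m_gt = np.stack([y[:, labels == g, :].mean(axis=1)
                     for g in (0, 1)], axis=1)                # (reps, 2, T)

    ss_between = T * ((m_s - mu[:, :, 0]) ** 2).sum(axis=1)
    ss_group = T * (n_g[None, :] * (m_g - mu[:, :, 0]) ** 2).sum(axis=1)
    ss_subj = ss_between - ss_group
    ss_within = ((y - m_s[:, :, None]) ** 2).sum(axis=(1, 2))
    ss_time = N * ((m_t - mu[:, 0, :]) ** 2).sum(axis=1)
    ss_cells = (n_g[None, :, None] * (m_gt - mu) ** 2).sum(axis=(1, 2))
    ss_inter = ss_cells - ss_group - ss_time
    ss_err = ss_within - ss_time - ss_inter

    G = 2
    df_group = G - 1
    df_subj = N - G
    df_time = T - 1
    df_inter = (G - 1) * (T - 1)
    df_err = (N - G) * (T - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_group = (ss_group / df_group) / (ss_subj / df_subj)
        f_time = (ss_time / df_time) / (ss_err / df_err)
        f_inter = (ss_inter / df_inter) / (ss_err / df_err)
    return {
        "f_group": f_group,
        "p_group": sps.f.sf(f_group, df_group, df_subj),
        "f_time": f_time,
        "p_time": sps.f.sf(f_time, df_time, df_err),
        "f_inter": f_inter,
        "p_inter": sps.f.sf(f_inter, df_inter, df_err),
        "df": {"group": (df_group, df_subj), "time": (df_time, df_err),
               "interaction": (df_inter, df_err)},
    }


def split_plot_group_f(y: np.ndarray, labels: np.ndarray):
    """Group-effect F and p of the split-plot model, vectorised over
    replicates: ``y`` (reps, N, T), ``labels`` (N,).  Used for Monte-Carlo
    calibration of the group test."""
    res = _split_plot(np.asarray(y, dtype=float), np.asarray(labels))
    return res["f_group"], res["p_group"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p_value: float
    df: int
    flagged: str | None = None


def two_group_t(a, b) -> TTestResult:
    """Pooled-variance two-sided Student t-test.

    Degenerate zero-variance data follow the conventions: equal means give
    p = 1, unequal means give p = 0 (flagged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    df = a.size + b.size - 2
    sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df)
    if sp2 == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p_value=1.0, df=df,
                               flagged="zero variance, equal means")
        return TTestResult(t=np.inf if a.mean() > b.mean() else -np.inf,
                           p_value=0.0, df=df,
                           flagged="zero variance, unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), p_value=float(p), df=df)
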