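"""Group-comparison statistics.

The inferential layer mirrors the standard small-sample toolkit for a
two-group behavioral study: one-way ANOVA on participant-level accuracy
and reaction time, pooled-variance two-sample t-tests on item-level
in-degree vectors (overall and within each valence stratum), and Pearson
correlations between accuracy and trait subscale scores.

The t-test defaults to the Student (pooled-variance) variant — its degrees
of freedom are ``n1 + n2 - 2`` — with Welch available as an option.  All
tests are two-sided.  No multiple-testing correction is applied across the
three valence strata by default; a Bonferroni option is provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import (
    VALENCES,
    AnswerKey,
    ResponseRecord,
    TraitRecord,
    ValidationError,
)
from .metrics import (
    in_degree_vector,
    network_density,
    participant_accuracy,
    participant_mean_rt,
)
from .network import ResponseNetwork


class DegenerateDataError(ValueError):
    """Statistic undefined for the given data (e.g. zero variance)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test or correlation."""

    statistic: str  # "F", "t" or "r"
    value: float
    df: tuple[int, ...] | int
    p_value: float
    group_summaries: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def format(self) -> str:
        df = self.df
        df_str = ", ".join(str(d) for d in df) if isinstance(df, tuple) else str(df)
        return (
            f"{self.statistic}({df_str}) = {self.value:.2f}, p = {self.p_value:.3f}"
        )


def _summaries(a: Sequence[float], b: Sequence[float]) -> dict[str, tuple[float, float]]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    return {
        "a": (float(a.mean()), float(a.std(ddof=1))),
        "b": (float(b.mean()), float(b.std(ddof=1))),
    }


def one_way_anova(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """One-way ANOVA for two groups; F with df (1, n1 + n2 - 2).

    For two groups F equals the square of the pooled two-sample t.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 values for ANOVA")
    df = (1, len(a) + len(b) - 2)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        # all observations identical: no variance to partition
        return TestResult("F", 0.0, df, 1.0, _summaries(a, b))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant within-group input
        f, p = sps.f_oneway(a, b)
    if math.isinf(f):
        return TestResult("F", math.inf, df, 0.0, _summaries(a, b))
    return TestResult("F", float(f), df, float(p), _summaries(a, b))


def two_sample_t(
    values_a: Sequence[float],
    values_b: Sequence[float],
    welch: bool = False,
) -> TestResult:
    """Two-sample t-test, Student pooled-variance by default.

    Zero pooled variance with unequal means yields an infinite-t sentinel
    (p = 0); with equal means, t = 0 and p = 1.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 values for a t-test")
    summaries = _summaries(a, b)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        df = len(a) + len(b) - 2
        if a.mean() == b.mean():
            return TestResult("t", 0.0, df, 1.0, summaries)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TestResult("t", sign * math.inf, df, 0.0, summaries)
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = int(res.df) if not welch else float(res.df)
    return TestResult("t", float(res.statistic), df, float(res.pvalue), summaries)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with two-sided p; df = n - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValidationError("Pearson correlation needs at least 3 complete pairs")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateDataError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return TestResult("r", float(res.statistic), len(x) - 2, float(res.pvalue))


# ---------------------------------------------------------------------------
# Full two-group comparison report
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Structured output of :func:`compare_groups`.

    ``behavioral`` holds the accuracy / reaction-time ANOVA block,
    ``network`` the node/edge/density summaries and in-degree t-tests
    (overall and per valence), and ``correlations`` the accuracy-vs-trait
    Pearson block.  ``to_text`` renders a human-readable report; ``write``
    emits the three blocks as CSVs plus the text rendering.
    """

    group_a: str
    group_b: str
    behavioral: pd.DataFrame
    network: pd.DataFrame
    correlations: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"Two-group comparison: {self.group_a} vs {self.group_b}",
            "",
            "Behavioral measures (one-way ANOVA)",
            self.behavioral.to_string(index=False),
            "",
            "Network measures (pooled two-sample t on item in-degrees)",
            self.network.to_string(index=False),
            "",
            "Correlations (Pearson, accuracy vs trait subscale)",
            (
                self.correlations.to_string(index=False)
                if len(self.correlations)
                else "(no trait data)"
            ),
        ]
        if self.notes:
            lines += ["", "Notes:"] + [f"- {n}" for n in self.notes]
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.behavioral.to_csv(outdir / "behavioral.csv", index=False)
        self.network.to_csv(outdir / "network.csv", index=False)
        self.correlations.to_csv(outdir / "correlations.csv", index=False)
        (outdir / "report.txt").write_text(self.to_text(), encoding="utf-8")


def _fmt_df(df) -> str:
    if isinstance(df, tuple):
        return "(" + ", ".join(str(d) for d in df) + ")"
    return str(df)


def compare_groups(
    net_a: ResponseNetwork,
    net_b: ResponseNetwork,
    key: AnswerKey,
    records_a: Sequence[ResponseRecord],
    records_b: Sequence[ResponseRecord],
    traits: Sequence[TraitRecord] | None = None,
    aq_subscale: str = "patterns",
    adir_subscale: str = "socio_emotional_reciprocity",
    welch: bool = False,
    bonferroni: bool = False,
) -> ComparisonReport:
    """Run the full two-group analysis and assemble a report.

    Both networks must be built from the same answer key.  The behavioral
    block compares participant accuracy and mean reaction time by one-way
    ANOVA; the network block reports node/edge counts, densities, and
    t-tests on the in-degree vectors overall and per valence stratum
    (strata with fewer than 2 items are skipped with a note); the
    correlation block relates accuracy to the named AQ and ADI-R subscales
    within each group that has at least 3 scored participants.
    """
    notes: list[str] = []
    ga, gb = net_a.group, net_b.group
    if ga == gb:
        raise ValidationError("compare_groups needs two distinct groups")

    # --- behavioral block -------------------------------------------------
    def _participants(records: Sequence[ResponseRecord]) -> list[str]:
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.participant_id, None)
        return list(seen)

    pids_a, pids_b = _participants(records_a), _participants(records_b)
    acc_a = [participant_accuracy(records_a, key, p) for p in pids_a]
    acc_b = [participant_accuracy(records_b, key, p) for p in pids_b]
    acc = {p: v for p, v in zip(pids_a + pids_b, acc_a + acc_b)}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-timeout participants excluded
        rt_a = [participant_mean_rt(records_a, p) for p in pids_a]
        rt_b = [participant_mean_rt(records_b, p) for p in pids_b]
    rt_a = [v for v in rt_a if v is not None]
    rt_b = [v for v in rt_b if v is not None]

    behavioral_rows = []
    for measure, va, vb in (("accuracy", acc_a, acc_b), ("reaction_time_ms", rt_a, rt_b)):
        res = one_way_anova(va, vb)
        behavioral_rows.append(
            {
                "measure": measure,
                f"mean_{ga}": res.group_summaries["a"][0],
                f"sd_{ga}": res.group_summaries["a"][1],
                f"mean_{gb}": res.group_summaries["b"][0],
                f"sd_{gb}": res.group_summaries["b"][1],
                "statistic": "F",
                "value": res.value,
                "df": _fmt_df(res.df),
                "p_value": res.p_value,
            }
        )
    behavioral = pd.DataFrame(behavioral_rows)

    # --- network block ----------------------------------------------------
    network_rows = [
        {
            "row": "n_nodes",
            ga: net_a.n_nodes,
            gb: net_b.n_nodes,
            "statistic": "",
            "value": np.nan,
            "df": "",
            "p_value": np.nan,
        },
        {
            "row": "n_edges",
            ga: net_a.n_edges,
            gb: net_b.n_edges,
            "statistic": "",
            "value": np.nan,
            "df": "",
            "p_value": np.nan,
        },
        {
            "row": "network_density",
            ga: network_density(net_a, digits=3),
            gb: network_density(net_b, digits=3),
            "statistic": "",
            "value": np.nan,
            "df": "",
            "p_value": np.nan,
        },
    ]

    strata: list[tuple[str, str | None]] = [("in_degree_all", None)]
    valence_counts = key.valence_counts()
    strata += [(f"in_degree_{v}", v) for v in VALENCES if valence_counts[v] > 0]
    n_strata_tested = 0
    stratum_rows = []
    for label, valence in strata:
        va = in_degree_vector(net_a, key, valence)
        vb = in_degree_vector(net_b, key, valence)
        if len(va) < 2:
            notes.append(
                f"{label}: stratum has {len(va)} item(s); t-test skipped (needs >= 2)"
            )
            continue
        res = two_sample_t(va, vb, welch=welch)
        if valence is not None:
            n_strata_tested += 1
        stratum_rows.append((label, valence, res))
    for label, valence, res in stratum_rows:
        p = res.p_value
        if bonferroni and valence is not None:
            p = min(1.0, p * max(n_strata_tested, 1))
        network_rows.append(
            {
                "row": label,
                ga: f"{res.group_summaries['a'][0]:.2f} ± {res.group_summaries['a'][1]:.2f}",
                gb: f"{res.group_summaries['b'][0]:.2f} ± {res.group_summaries['b'][1]:.2f}",
                "statistic": "t",
                "value": res.value,
                "df": _fmt_df(res.df),
                "p_value": p,
            }
        )
    if bonferroni:
        notes.append(
            f"Bonferroni correction applied across {n_strata_tested} valence strata"
        )
    else:
        notes.append("no multiple-testing correction across valence strata")
    network = pd.DataFrame(network_rows)

    # --- correlation block ------------------------------------------------
    corr_rows = []
    if traits:
        by_group: dict[str, list[TraitRecord]] = {}
        for t in traits:
            by_group.setdefault(t.group, []).append(t)
        for g in (ga, gb):
            for scale_kind, scale_name in (("aq", aq_subscale), ("adir", adir_subscale)):
                recs = by_group.get(g, [])
                pairs = [
                    (acc[t.participant_id], getattr(t, scale_kind).get(scale_name))
                    for t in recs
                    if t.participant_id in acc
                    and getattr(t, scale_kind).get(scale_name) is not None
                ]
                if len(pairs) < 3:
                    if recs:
                        notes.append(
                            f"group {g}: <3 participants with {scale_kind}_{scale_name}; "
                            "correlation skipped"
                        )
                    continue
                x, y = zip(*pairs)
                try:
                    res = pearson_r(x, y)
                except DegenerateDataError:
                    notes.append(
                        f"group {g}: constant {scale_kind}_{scale_name}; "
                        "correlation undefined"
                    )
                    continue
                corr_rows.append(
                    {
                        "group": g,
                        "x": "accuracy",
                        "y": f"{scale_kind}_{scale_name}",
                        "r": res.value,
                        "df": res.df,
                        "p_value": res.p_value,
                        "n": res.df + 2,
                    }
                )
    else:
        notes.append("no trait table provided; correlation block omitted")
    correlations = pd.DataFrame(
        corr_rows, columns=["group", "x", "y", "r", "df", "p_value", "n"]
    )

    return ComparisonReport(
        group_a=ga,
        group_b=gb,
        behavioral=behavioral,
        network=network,
        correlations=correlations,
        notes=notes,
    )
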