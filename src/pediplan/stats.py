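"""Group-comparison statistics for screw-placement cohorts.

Two tests back the comparison between a planned cohort and an implanted
("freehand") cohort:

* paired two-sided t-tests on screw length and diameter (pairing by screw
  site), computed from the textbook formula t = mean(d) / (sd(d)/sqrt(n))
  with df = n - 1;
* Fisher's exact test on the 2x2 table of grade-A vs other placements,
  two-sided under the probability-ordering definition: the p-value is the
  sum of hypergeometric probabilities of all tables (same margins) no more
  probable than the observed one.

Grade tallies are summarised per group and side with grade-A proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
import json
import math

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .errors import DegenerateTestError, FormatError, PairingError

GRADES = ("A", "B", "C", "D", "E")
SIDES = ("L", "R")


# ---------------------------------------------------------------------------
# Paired t-test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedSample:
    values_a: tuple
    values_b: tuple

    def __post_init__(self):
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
            raise ValueError("paired sample needs two equal-length lists, n >= 2")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired sample values must be finite")
        object.__setattr__(self, "values_a", tuple(a))
        object.__setattr__(self, "values_b", tuple(b))


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float


def paired_t(sample: PairedSample) -> PairedTResult:
    """Two-sided paired t-test on the index-paired differences a - b."""
    d = np.asarray(sample.values_a) - np.asarray(sample.values_b)
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateTestError("all paired differences are equal: t undefined")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return PairedTResult(t=float(t), df=df, p=float(p), mean_diff=float(d.mean()))


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = groups, columns = grade A vs other."""

    a11: int
    a12: int
    a21: int
    a22: int

    def __post_init__(self):
        cells = (self.a11, self.a12, self.a21, self.a22)
        if any(int(c) != c or c < 0 for c in cells):
            raise ValueError("table cells must be non-negative integers")
        if sum(cells) == 0:
            raise DegenerateTestError("all-zero contingency table")


def _log_hypergeom_pmf(k, row1, col1, total):
    """log P(X = k) for X ~ Hypergeometric(total, col1, row1)."""
    return (
        gammaln(row1 + 1)
        - gammaln(k + 1)
        - gammaln(row1 - k + 1)
        + gammaln(total - row1 + 1)
        - gammaln(col1 - k + 1)
        - gammaln(total - row1 - col1 + k + 1)
        - (gammaln(total + 1) - gammaln(col1 + 1) - gammaln(total - col1 + 1))
    )


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher p (probability ordering) via log-factorials."""
    row1 = table.a11 + table.a12
    col1 = table.a11 + table.a21
    total = row1 + table.a21 + table.a22
    k_min = max(0, row1 + col1 - total)
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    logp = _log_hypergeom_pmf(ks, row1, col1, total)
    log_obs = _log_hypergeom_pmf(np.array([table.a11]), row1, col1, total)[0]
    # Relative tolerance absorbs float noise in "no more probable than".
    keep = logp <= log_obs + 1e-9
    return float(min(1.0, np.exp(logp[keep]).sum()))


# ---------------------------------------------------------------------------
# Grade summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradeSummary:
    """Per group x side grade counts with grade-A proportions (fractions)."""

    counts: dict  # group -> side -> grade -> int

    def side_total(self, group: str, side: str) -> int:
        return sum(self.counts[group][side].values())

    def group_total(self, group: str) -> int:
        return sum(self.side_total(group, s) for s in self.counts[group])

    def grade_total(self, group: str, grade: str) -> int:
        return sum(self.counts[group][s].get(grade, 0) for s in self.counts[group])

    def side_a_proportion(self, group: str, side: str) -> float:
        return self.counts[group][side].get("A", 0) / self.side_total(group, side)

    def overall_a_proportion(self, group: str) -> float:
        return self.grade_total(group, "A") / self.group_total(group)

    def to_text(self) -> str:
        lines = []
        for group, sides in self.counts.items():
            for side in sides:
                row = " ".join(f"{g}={sides[side].get(g, 0)}" for g in GRADES)
                lines.append(
                    f"{group} {side}: {row}  "
                    f"A-proportion {100 * self.side_a_proportion(group, side):.2f}%"
                )
            lines.append(
                f"{group} overall A-proportion "
                f"{100 * self.overall_a_proportion(group):.2f}%"
            )
        return "\n".join(lines)


def _grade_of(entry) -> str:
    grade = getattr(entry, "grade", entry)
    if grade not in GRADES:
        raise FormatError(f"unknown grade {grade!r}")
    return grade


def summarize_grades(grades) -> GradeSummary:
    """Tally (group, side, grade-or-GRResult) records into a GradeSummary."""
    grades = list(grades)
    if not grades:
        raise ValueError("no grades to summarize")
    counts: dict = {}
    for group, side, res in grades:
        if side not in SIDES:
            raise FormatError(f"unknown side {side!r}")
        g = _grade_of(res)
        counts.setdefault(group, {}).setdefault(side, {gr: 0 for gr in GRADES})
        counts[group][side][g] += 1
    return GradeSummary(counts=counts)


def a_vs_other_table(summary: GradeSummary, group_a: str, group_b: str) -> ContingencyTable2x2:
    """Collapse a summary into the grade-A-vs-other 2x2 table."""
    na, nb = summary.group_total(group_a), summary.group_total(group_b)
    ka, kb = summary.grade_total(group_a, "A"), summary.grade_total(group_b, "A")
    return ContingencyTable2x2(ka, na - ka, kb, nb - kb)


def load_table3_counts() -> GradeSummary:
    """The published clinical grade tallies (freehand vs planned, by side),
    packaged so the headline proportions and Fisher test are regression-
    testable without clinical data."""
    with resources.files("pediplan.data").joinpath("table3_counts.json").open() as fh:
        raw = json.load(fh)
    return GradeSummary(
        counts={
            group: {side: {g: int(c) for g, c in grades.items()} for side, grades in sides.items()}
            for group, sides in raw.items()
        }
    )


# ---------------------------------------------------------------------------
# Cohort comparison
# ---------------------------------------------------------------------------

def compare_groups(ai, freehand, group_names=("AI", "Freehand")) -> dict:
    """Full comparison report between two cohorts of screw records.

    Each cohort is an iterable of dicts (or a DataFrame converted with
    ``DataFrame.to_dict("records")``) with keys ``id, side, grade`` and
    optionally ``length_mm, diameter_mm``.  Records are paired by
    ``(id, side)`` for the t-tests; the Fisher test needs no pairing.

    The report contains per-side and pooled paired t-tests on length and
    diameter (flagged rather than raised when degenerate or unpairable) and
    the grade-A-vs-other Fisher test.
    """
    name_a, name_b = group_names
    ai = [dict(r) for r in ai]
    freehand = [dict(r) for r in freehand]

    summary = summarize_grades(
        [(name_a, r["side"], r["grade"]) for r in ai]
        + [(name_b, r["side"], r["grade"]) for r in freehand]
    )
    table = a_vs_other_table(summary, name_a, name_b)
    report = {
        "grade_summary": summary,
        "table_a_vs_other": table,
        "fisher_p": fisher_exact_2x2(table),
        "paired_tests": {},
    }

    def records_by_key(rows):
        by = {}
        for r in rows:
            key = (r["id"], r["side"])
            if key in by:
                raise PairingError(f"duplicate record for {key}")
            by[key] = r
        return by

    try:
        by_a, by_b = records_by_key(ai), records_by_key(freehand)
        common = sorted(set(by_a) & set(by_b))
        if not common or len(common) != len(by_a) or len(common) != len(by_b):
            raise PairingError(
                f"cohorts are not one-to-one pairable "
                f"({len(by_a)} vs {len(by_b)} records, {len(common)} matched)"
            )
    except PairingError as exc:
        report["paired_tests"]["error"] = str(exc)
        return report

    for quantity in ("length_mm", "diameter_mm"):
        if not all(quantity in by_a[k] and quantity in by_b[k] for k in common):
            continue
        for scope in ("L", "R", "pooled"):
            keys = [k for k in common if scope == "pooled" or k[1] == scope]
            if len(keys) < 2:
                continue
            sample = PairedSample(
                tuple(float(by_a[k][quantity]) for k in keys),
                tuple(float(by_b[k][quantity]) for k in keys),
            )
            try:
                res = paired_t(sample)
                entry = {
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "mean_diff": res.mean_diff,
                    "n_pairs": len(keys),
                    "significant_at_0.05": res.p < 0.05,
                }
            except DegenerateTestError as exc:
                entry = {"degenerate": str(exc), "n_pairs": len(keys)}
            report["paired_tests"][f"{quantity}/{scope}"] = entry
    return report
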