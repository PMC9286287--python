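"""Five-category differential-rhythmicity classification.

Each gene carries four statistics: a rhythm adjusted p per group (group 1
is the test condition, e.g. the knockout; group 2 the reference), a
between-group meta p, and the circular difference of the two peak phases.
An ordered rule table — thresholds adjP 0.05 / 0.1, meta p 0.01, phase
6 h — assigns exactly one category:

    rhythmic_both_unchanged, rhythmic_both_phase_change,
    rhythmic_both_other_difference, gained_in_g1_only, lost_in_g1,

with a terminal ``unclassified`` catch-all (both groups arrhythmic, or
boundary-zone statistics matching no rule).  Rules are data, not code:
thresholds and inequality directions are configurable, and two presets
are shipped because the published criteria admit two readings of the
meta-p direction (see ``default_rule_table``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneStats",
    "Rule",
    "RuleTable",
    "GeneClassification",
    "CATEGORIES",
    "circular_phase_diff",
    "default_rule_table",
    "classify_gene",
    "classify_all",
]

CATEGORIES = (
    "rhythmic_both_unchanged",
    "rhythmic_both_phase_change",
    "rhythmic_both_other_difference",
    "gained_in_g1_only",
    "lost_in_g1",
    "unclassified",
)

_FIELDS = ("adjp_g1", "adjp_g2", "meta_p", "phase_diff")
_OPS = {"<": lambda x, thr: x < thr, ">": lambda x, thr: x > thr}


@dataclass(frozen=True)
class GeneStats:
    """Joined per-gene inputs to the classifier.

    Phases may be NaN when the corresponding group is arrhythmic; any
    rule predicate on the phase difference then fails to match.
    """

    gene_id: str
    adjp_g1: float
    adjp_g2: float
    meta_p: float
    phase_g1_h: float = math.nan
    phase_g2_h: float = math.nan

    @property
    def phase_diff_h(self) -> float:
        if math.isnan(self.phase_g1_h) or math.isnan(self.phase_g2_h):
            return math.nan
        return circular_phase_diff(self.phase_g1_h, self.phase_g2_h)


@dataclass(frozen=True)
class Rule:
    """Conjunction of strict threshold predicates; fields not listed are unused."""

    category: str
    predicates: tuple[tuple[str, str, float], ...]  # (field, '<' or '>', threshold)

    def matches(self, adjp_g1, adjp_g2, meta_p, phase_diff) -> bool:
        vals = {
            "adjp_g1": adjp_g1,
            "adjp_g2": adjp_g2,
            "meta_p": meta_p,
            "phase_diff": phase_diff,
        }
        for fld, op, thr in self.predicates:
            x = vals[fld]
            if x is None or (isinstance(x, float) and math.isnan(x)):
                return False
            if not _OPS[op](x, thr):
                return False
        return True


@dataclass(frozen=True)
class RuleTable:
    """Ordered rules; the first match wins; a catch-all ends the table."""

    rules: tuple[Rule, ...]
    orientation: str = "as_printed"

    def __post_init__(self):
        if not self.rules or self.rules[-1].category != "unclassified":
            raise ValueError("rule table must end with the unclassified catch-all")
        for r in self.rules:
            for fld, op, _ in r.predicates:
                if fld not in _FIELDS or op not in _OPS:
                    raise ValueError(f"bad predicate {fld!r} {op!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, r in enumerate(self.rules):
            rows.append(
                {
                    "rule": k,
                    "category": r.category,
                    **{f"{fld}": f"{op} {thr}" for fld, op, thr in r.predicates},
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GeneClassification:
    gene_id: str
    category: str
    matched_rule: int


def circular_phase_diff(phi1_h: float, phi2_h: float, cycle_h: float = 24.0) -> float:
    """Shorter-arc distance between two clock phases, in [0, cycle/2]."""
    if not (np.isfinite(phi1_h) and np.isfinite(phi2_h)):
        raise ValueError("phases must be finite; undefined phases never reach here")
    d = abs(phi1_h - phi2_h) % cycle_h
    return float(min(d, cycle_h - d))


def default_rule_table(
    orientation: str = "as_printed",
    adjp1: float = 0.05,
    adjp2: float = 0.1,
    metap: float = 0.01,
    phase_h: float = 6.0,
) -> RuleTable:
    """The published five-row decision table, plus the catch-all.

    ``as_printed`` reproduces the printed inequalities verbatim:
    "unchanged" requires meta p < 0.01 while the change categories require
    meta p > 0.01.  ``difference_consistent`` flips the meta-p direction
    in those four rows so that categories asserting a rhythm difference
    demand a small meta p and "unchanged" a large one — the orientation a
    difference-detecting null implies.  The phase-change row uses no
    meta-p predicate in either preset, and the gained/lost rows carry no
    phase predicate (one group has no defined peak).
    """
    if orientation not in ("as_printed", "difference_consistent"):
        raise ValueError("orientation must be as_printed or difference_consistent")
    flip = orientation == "difference_consistent"
    lt, gt = "<", ">"
    meta_unchanged = (gt if flip else lt)
    meta_changed = (lt if flip else gt)
    rules = (
        Rule(
            "rhythmic_both_unchanged",
            (
                ("adjp_g1", lt, adjp1),
                ("adjp_g2", lt, adjp2),
                ("meta_p", meta_unchanged, metap),
                ("phase_diff", lt, phase_h),
            ),
        ),
        Rule(
            "rhythmic_both_phase_change",
            (
                ("adjp_g1", lt, adjp1),
                ("adjp_g2", lt, adjp2),
                ("phase_diff", gt, phase_h),
            ),
        ),
        Rule(
            "rhythmic_both_other_difference",
            (
                ("adjp_g1", lt, adjp1),
                ("adjp_g2", lt, adjp2),
                ("meta_p", meta_changed, metap),
                ("phase_diff", lt, phase_h),
            ),
        ),
        Rule(
            "gained_in_g1_only",
            (
                ("adjp_g1", lt, adjp1),
                ("adjp_g2", gt, adjp2),
                ("meta_p", meta_changed, metap),
            ),
        ),
        Rule(
            "lost_in_g1",
            (
                ("adjp_g1", gt, adjp2),
                ("adjp_g2", lt, adjp1),
                ("meta_p", meta_changed, metap),
            ),
        ),
        Rule("unclassified", ()),
    )
    return RuleTable(rules=rules, orientation=orientation)


def classify_gene(stats: GeneStats, rules: RuleTable) -> GeneClassification:
    """First matching rule wins; the catch-all guarantees a label."""
    d = stats.phase_diff_h
    for k, rule in enumerate(rules.rules):
        if rule.matches(stats.adjp_g1, stats.adjp_g2, stats.meta_p, d):
            return GeneClassification(stats.gene_id, rule.category, k)
    raise AssertionError("unreachable: catch-all rule always matches")


def classify_all(
    stats_table: pd.DataFrame, rules: RuleTable
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify a joined statistics table.

    ``stats_table`` needs columns gene_id, adjp_g1, adjp_g2, meta_p,
    phase_g1_h, phase_g2_h.  Returns the per-gene classification frame
    (with the phase difference and matched rule) and the category counts,
    which partition the input.
    """
    if stats_table["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_ids in classifier input")
    rows = []
    for rec in stats_table.itertuples(index=False):
        st = GeneStats(
            gene_id=str(rec.gene_id),
            adjp_g1=float(rec.adjp_g1),
            adjp_g2=float(rec.adjp_g2),
            meta_p=float(rec.meta_p),
            phase_g1_h=float(getattr(rec, "phase_g1_h", math.nan)),
            phase_g2_h=float(getattr(rec, "phase_g2_h", math.nan)),
        )
        cl = classify_gene(st, rules)
        rows.append(
            {
                "gene_id": st.gene_id,
                "category": cl.category,
                "matched_rule": cl.matched_rule,
                "adjp_g1": st.adjp_g1,
                "adjp_g2": st.adjp_g2,
                "meta_p": st.meta_p,
                "phase_g1_h": st.phase_g1_h,
                "phase_g2_h": st.phase_g2_h,
                "phase_diff_h": st.phase_diff_h,
            }
        )
    out = pd.DataFrame(rows)
    counts = (
        out["category"].value_counts().reindex(CATEGORIES, fill_value=0).astype(int)
    )
    counts.name = "n_genes"
    return out, counts
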