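"""Comparison-intersection signature lists and the developmental patterns.

All operations work on gene-level status tables (index = gene symbol,
``status`` column) sharing the same gene universe.  Two strictness modes
govern what counts as "downregulated or not differentially expressed":

* ``lenient`` (default): any status other than DE in the forbidden
  direction (so SIGNIFICANT-but-sub-twofold and UNCERTAIN genes qualify);
* ``strict``: only DE_DOWN or UNCHANGED qualify.

The lenient default reflects that a sub-twofold significant course in the
tissue-mix comparison does not disqualify a gene from the thyroid-specific
lists.

The pattern classifier maps each gene's status triple over comparisons
1 (AT-ET), 3 (AM-EM) and 4 (ET-EM) onto the four developmental programs:

======== ======== ================= ========
pattern  comp4    comp3             comp1
======== ======== ================= ========
I        DE_UP    eligible-down     DE_UP
II       DE_UP    eligible-down     UNCHANGED
III      DE_UP    eligible-down     DE_DOWN
IV       UNCHANGED eligible-down    DE_UP
======== ======== ================= ========

with eligible-down = {DE_DOWN, UNCHANGED} by default.  The patterns are
mutually exclusive; genes matching none are labelled NONE.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .io import ValidationError

DE_STATUSES = frozenset({"DE_UP", "DE_DOWN"})
ELIGIBLE_DOWN_DEFAULT = frozenset({"DE_DOWN", "UNCHANGED"})
PATTERNS = ("I", "II", "III", "IV")


@dataclasses.dataclass
class SignatureLists:
    """Gene sets from the comparison-2 x comparison-4 intersection."""

    coregulated_up: set[str]
    coregulated_down: set[str]
    opposite: set[str]
    at_specific_up: set[str]
    et_specific_up: set[str]
    strictness: str

    def counts(self) -> dict[str, int]:
        return {
            "coregulated_up": len(self.coregulated_up),
            "coregulated_down": len(self.coregulated_down),
            "opposite": len(self.opposite),
            "at_specific_up": len(self.at_specific_up),
            "et_specific_up": len(self.et_specific_up),
        }


def _check_universe(*tables: pd.DataFrame) -> pd.Index:
    base = tables[0].index
    for t in tables[1:]:
        if not base.equals(t.index):
            asym = sorted(set(base.symmetric_difference(t.index)))
            raise ValidationError(
                f"status tables cover different gene universes; "
                f"{len(asym)} asymmetric genes, e.g. {asym[:5]}"
            )
    return base


def _not_up(status: str, strictness: str) -> bool:
    if strictness == "strict":
        return status in ("DE_DOWN", "UNCHANGED")
    return status != "DE_UP"


def _not_de(status: str, strictness: str) -> bool:
    if strictness == "strict":
        return status == "UNCHANGED"
    return status not in DE_STATUSES


def intersect_signatures(
    status2: pd.DataFrame,
    status4: pd.DataFrame,
    strictness: str = "lenient",
) -> SignatureLists:
    """Adult/embryonic thyroid signature algebra over comparisons 2 and 4.

    coregulated = DE in the same direction in both thyroid-vs-mix
    comparisons; opposite = DE in both with opposite signs; at_specific_up =
    up in the adult thyroid comparison while down or not differentially
    expressed in the embryonic one (per strictness); et_specific_up
    symmetric.  A gene may appear in both ``opposite`` and a specific list.
    """
    if strictness not in ("strict", "lenient"):
        raise ValueError(f"unknown strictness {strictness!r}")
    genes = _check_universe(status2, status4)
    s2 = status2["status"]
    s4 = status4["status"]
    lists = SignatureLists(set(), set(), set(), set(), set(), strictness)
    for g in genes:
        a, b = s2[g], s4[g]
        if a == "DE_UP" and b == "DE_UP":
            lists.coregulated_up.add(g)
        if a == "DE_DOWN" and b == "DE_DOWN":
            lists.coregulated_down.add(g)
        if a in DE_STATUSES and b in DE_STATUSES and a != b:
            lists.opposite.add(g)
        if a == "DE_UP" and _not_up(b, strictness):
            lists.at_specific_up.add(g)
        if b == "DE_UP" and _not_up(a, strictness):
            lists.et_specific_up.add(g)
    return lists


def thyroid_specific_developmental(
    status1: pd.DataFrame,
    status3: pd.DataFrame,
    strictness: str = "lenient",
) -> set[str]:
    """Genes developmentally regulated in the thyroid but not in other tissues.

    DE in either direction in comparison 1 (AT-ET) while not DE (lenient) /
    strictly unchanged (strict) in comparison 3 (AM-EM) -- excluding the
    genes regulated in thyroid and non-thyroid tissues alike.
    """
    if strictness not in ("strict", "lenient"):
        raise ValueError(f"unknown strictness {strictness!r}")
    genes = _check_universe(status1, status3)
    s1 = status1["status"]
    s3 = status3["status"]
    return {
        g for g in genes
        if s1[g] in DE_STATUSES and _not_de(s3[g], strictness)
    }


def assign_patterns(
    status1: pd.DataFrame,
    status3: pd.DataFrame,
    status4: pd.DataFrame,
    eligible_down_set: frozenset[str] = ELIGIBLE_DOWN_DEFAULT,
) -> pd.DataFrame:
    """Classify every gene into developmental pattern I-IV or NONE.

    Returns a table indexed by gene with the assigned ``pattern`` and the
    contributing status triple.  The mapping is deterministic and the
    patterns are mutually exclusive by construction.
    """
    genes = _check_universe(status1, status3, status4)
    s1 = status1["status"]
    s3 = status3["status"]
    s4 = status4["status"]
    patterns = []
    for g in genes:
        a, b, c = s1[g], s3[g], s4[g]
        label = "NONE"
        if b in eligible_down_set:
            if c == "DE_UP":
                if a == "DE_UP":
                    label = "I"
                elif a == "UNCHANGED":
                    label = "II"
                elif a == "DE_DOWN":
                    label = "III"
            elif c == "UNCHANGED" and a == "DE_UP":
                label = "IV"
        patterns.append(label)
    return pd.DataFrame(
        {
            "pattern": patterns,
            "comp1_status": s1.loc[genes].to_numpy(),
            "comp3_status": s3.loc[genes].to_numpy(),
            "comp4_status": s4.loc[genes].to_numpy(),
        },
        index=genes,
    )


def pattern_counts(assignments: pd.DataFrame) -> dict[str, int]:
    counts = assignments["pattern"].value_counts().to_dict()
    return {p: int(counts.get(p, 0)) for p in (*PATTERNS, "NONE")}
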