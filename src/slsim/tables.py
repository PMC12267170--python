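"""Printed cohort and node-distribution tables of the source study.

The study reports four hospital cohorts (training, internal validation,
testing and external validation) with per-Schatzker-type counts, and a
three-node distribution of the training pool in two regimes: *balanced*
(stratified, IID) and *unbalanced* (each fracture class exclusive to one
node, non-IID).

These constants reproduce every printed cell as published.  The printed
tables contain two internal inconsistencies, which are kept as printed and
surfaced by :func:`consistency_report` rather than silently reconciled:

* the node-distribution table's class-K total is 94 while the training
  cohort lists 95 type-K patients, so the three node totals sum to 3,026
  against a training cohort of 3,027;
* the external cohort's per-type fracture counts sum to 392 although the
  cohort is described as 400 fracture and 400 control images (总 800);
  :func:`external_composition` therefore rescales the printed fracture mix
  to 400 by largest remainder when an exactly balanced external fixture is
  requested.
"""

from __future__ import annotations

from typing import Mapping

from .partition import apportion

#: Schatzker-type counts per cohort, as printed.  Types I..VI plus the
#: intercondylar ridge type K and controls.
TABLE1_TYPES: dict[str, dict[str, int]] = {
    "train": {"I": 195, "II": 320, "III": 169, "IV": 181, "V": 225, "VI": 200, "K": 95, "NEG": 1642},
    "val": {"I": 25, "II": 42, "III": 18, "IV": 23, "V": 33, "VI": 20, "K": 11, "NEG": 205},
    "test": {"I": 24, "II": 40, "III": 20, "IV": 23, "V": 40, "VI": 13, "K": 12, "NEG": 205},
    "external": {"I": 92, "II": 64, "III": 50, "IV": 76, "V": 42, "VI": 20, "K": 48, "NEG": 400},
}

#: Printed cohort headcounts ("N patients in cohort").
TABLE1_TOTALS: dict[str, int] = {"train": 3027, "val": 377, "test": 377, "external": 800}

#: Schatzker type -> six-class label.
TYPE_TO_CLASS: dict[str, str] = {
    "I": "A", "II": "B", "III": "B", "IV": "C", "V": "D", "VI": "D", "K": "K", "NEG": "NEG",
}

#: Balanced (IID) node distribution of the training pool: class -> counts
#: for nodes 1..3, as printed.
TABLE2_BALANCED: dict[str, tuple[int, int, int]] = {
    "A": (94, 57, 44),
    "B": (249, 133, 107),
    "C": (83, 61, 37),
    "D": (217, 135, 73),
    "K": (49, 29, 16),
    "NEG": (821, 493, 328),
}

#: Unbalanced (non-IID) node distribution: every fracture class lives on
#: exactly one node; controls are split 907:325:410.
TABLE2_UNBALANCED: dict[str, tuple[int, int, int]] = {
    "A": (0, 0, 195),
    "B": (0, 489, 0),
    "C": (181, 0, 0),
    "D": (425, 0, 0),
    "K": (0, 94, 0),
    "NEG": (907, 325, 410),
}

#: Printed node headcounts for both distributions.
TABLE2_NODE_TOTALS: tuple[int, int, int] = (1513, 908, 605)

#: Which node holds each fracture class in the unbalanced regime (0-based).
UNBALANCED_CLASS_NODE: dict[str, int] = {"C": 0, "D": 0, "B": 1, "K": 1, "A": 2}

#: Control split across nodes in the unbalanced regime.
UNBALANCED_NEG_SPLIT: tuple[int, int, int] = (907, 325, 410)


def cohort_composition(cohort: str) -> dict[str, int]:
    """Six-class composition of a printed cohort (types merged per class)."""
    types = TABLE1_TYPES[cohort]
    out: dict[str, int] = {}
    for t, n in types.items():
        c = TYPE_TO_CLASS[t]
        out[c] = out.get(c, 0) + n
    return out


def external_composition() -> dict[str, int]:
    """An exactly balanced 400-fracture / 400-control external fixture.

    The printed external fracture types sum to 392, not the described 400;
    the printed mix is rescaled to 400 by largest remainder so the fixture
    matches the described cohort size of 800.
    """
    printed = cohort_composition("external")
    frac = {c: printed[c] for c in ("A", "B", "C", "D", "K")}
    sizes = apportion(400, list(frac.values()))
    out = dict(zip(frac, (int(s) for s in sizes)))
    out["NEG"] = 400
    return out


def scaled_composition(total: int, base: Mapping[str, int] | None = None) -> dict[str, int]:
    """Scale a composition to ``total`` images by largest remainder.

    Defaults to the training-cohort class mix, which is the desk-scale
    stand-in for the full 3,027-image training pool.
    """
    base = dict(base) if base is not None else cohort_composition("train")
    labels = list(base)
    sizes = apportion(int(total), [base[c] for c in labels])
    return {c: int(s) for c, s in zip(labels, sizes)}


def consistency_report() -> dict[str, object]:
    """Cross-check every printed cell against the printed headers.

    Returns a dict of named checks; ``True`` means the table is internally
    consistent, and the two known printed discrepancies are reported with
    their actual sums.
    """
    report: dict[str, object] = {}
    for cohort, types in TABLE1_TYPES.items():
        report[f"cohort_{cohort}_sum_matches_header"] = (
            sum(types.values()) == TABLE1_TOTALS[cohort]
        )
        report[f"cohort_{cohort}_type_sum"] = sum(types.values())
    report["study_total"] = sum(TABLE1_TOTALS.values())

    for name, table in (("balanced", TABLE2_BALANCED), ("unbalanced", TABLE2_UNBALANCED)):
        node_sums = tuple(sum(v[i] for v in table.values()) for i in range(3))
        report[f"{name}_node_sums"] = node_sums
        report[f"{name}_node_sums_match_headers"] = node_sums == TABLE2_NODE_TOTALS
        report[f"{name}_pool_total"] = sum(node_sums)
    # known printed discrepancies, kept as printed
    report["known_discrepancy_class_K"] = (
        sum(TABLE2_BALANCED["K"]),  # 94 in the node table
        TABLE1_TYPES["train"]["K"],  # 95 in the cohort table
    )
    report["known_discrepancy_external_fracture_sum"] = sum(
        v for t, v in TABLE1_TYPES["external"].items() if t != "NEG"
    )
    return report
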