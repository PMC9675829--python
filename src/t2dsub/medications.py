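"""Free-text medication annotation and group-differential usage tests.

Questionnaire entries ("Lipitor 20mg", "METFORMIN") are mapped to active
molecules and ATC codes through a synonym dictionary by exact matching after
normalization (lower-casing, punctuation stripping); fuzzy matching is
deliberately excluded to keep behaviour auditable.  Usage differences
between groups (cases vs controls, or one subtype vs the rest) are tested
per molecule or ATC level with two-sided Fisher exact tests.

A small toy dictionary (~40 molecules across the A10, C07, C09, C10, B01,
N02, M01 classes) ships with the package; a full drug database can be
supplied in the same three-column TSV format (synonym, molecule,
semicolon-separated ATC codes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_or

from .association import bonferroni_threshold

__all__ = [
    "ATC_PATTERN",
    "load_dictionary",
    "normalize_entry",
    "MedicationTable",
    "annotate_medications",
    "fisher_exact_2x2",
    "enrichment_scan",
]

#: ATC code grammar at the 1/3/4/5/7-character levels.
ATC_PATTERN = re.compile(
    r"^[A-Z]$|^[A-Z]\d{2}$|^[A-Z]\d{2}[A-Z]$|^[A-Z]\d{2}[A-Z]{2}$|^[A-Z]\d{2}[A-Z]{2}\d{2}$"
)

_PUNCT = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")


def normalize_entry(text: str) -> str:
    """Lower-case, strip punctuation, collapse whitespace."""
    return _WS.sub(" ", _PUNCT.sub(" ", str(text).lower())).strip()


def load_dictionary(path=None) -> pd.DataFrame:
    """Load a synonym dictionary (columns: synonym, molecule, atc_codes).

    Defaults to the packaged toy dictionary.  ATC codes are validated
    against the ATC level grammar; malformed rows raise.
    """
    if path is None:
        source = resources.files("t2dsub.data") / "atc_dictionary.tsv"
        with resources.as_file(source) as p:
            d = pd.read_csv(p, sep="\t", dtype=str)
    else:
        d = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"synonym", "molecule", "atc_codes"}
    if set(d.columns) != expected or d.isna().any().any():
        raise ValueError(
            f"malformed dictionary: need complete columns {sorted(expected)}"
        )
    for codes in d["atc_codes"]:
        for code in codes.split(";"):
            if not ATC_PATTERN.match(code):
                raise ValueError(f"malformed ATC code {code!r} in dictionary")
    d["synonym"] = d["synonym"].map(normalize_entry)
    return d


@dataclass
class MedicationTable:
    """Annotated per-subject medication usage.

    ``records`` has one row per distinct subject-molecule pair (columns:
    subject_id, molecule, atc_codes); ``unmatched`` keeps the raw strings
    that matched no dictionary synonym.
    """

    records: pd.DataFrame
    unmatched: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["subject_id", "entry"])
    )
    subject_ids: list = field(default_factory=list)

    def users(self, code: str, level: str = "molecule") -> set:
        """Subjects using a molecule or any drug under an ATC prefix."""
        if level == "molecule":
            sel = self.records["molecule"] == code
        else:
            sel = self.records["atc_codes"].map(
                lambda cs: any(c.startswith(code) for c in cs.split(";"))
            )
        return set(self.records.loc[sel, "subject_id"])


def annotate_medications(
    entries: pd.DataFrame, dictionary: pd.DataFrame | None = None
) -> MedicationTable:
    """Map free-text entries (columns: subject_id, entry) to molecules.

    Matching is exact after normalization, at whole-word granularity, so
    "Metformin 500mg" matches the synonym "metformin".  Repeat entries of a
    molecule collapse to one subject-molecule record; unmatched strings are
    kept with the subject id.
    """
    if dictionary is None:
        dictionary = load_dictionary()
    atc_by_molecule = (
        dictionary.drop_duplicates("molecule").set_index("molecule")["atc_codes"]
    )
    # longest synonyms first so multi-word names win over embedded single words
    synonyms = sorted(
        dictionary[["synonym", "molecule"]].itertuples(index=False),
        key=lambda r: -len(r.synonym),
    )
    matched: set[tuple] = set()
    unmatched_rows = []
    for row in entries.itertuples(index=False):
        text = normalize_entry(row.entry)
        hit = None
        padded = f" {text} "
        for syn in synonyms:
            if f" {syn.synonym} " in padded:
                hit = syn.molecule
                break
        if hit is None:
            unmatched_rows.append({"subject_id": row.subject_id, "entry": row.entry})
        else:
            matched.add((row.subject_id, hit))
    records = pd.DataFrame(
        sorted(matched), columns=["subject_id", "molecule"]
    )
    records["atc_codes"] = records["molecule"].map(atc_by_molecule)
    return MedicationTable(
        records=records,
        unmatched=pd.DataFrame(unmatched_rows, columns=["subject_id", "entry"]),
        subject_ids=sorted(set(entries["subject_id"])),
    )


def fisher_exact_2x2(table) -> tuple[float, float]:
    """(conditional odds ratio, two-sided Fisher exact p) for a 2x2 table.

    The two-sided p sums hypergeometric probabilities no larger than the
    observed table's.  A zero row or column margin makes the table
    uninformative: p = 1 and the odds ratio is NaN-flagged.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = np.asarray(table, dtype=float)
        if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("table must be 2x2 with non-negative integer counts")
        t = t.astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return np.nan, 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    orr = _conditional_or(t).statistic
    return float(orr), float(p)


def enrichment_scan(
    med_table: MedicationTable,
    groups: pd.Series,
    level: str = "molecule",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of drug usage in each group versus the rest.

    ``groups`` maps subject id to a group label (case/control, or subtype
    names over T2D cases); only subjects present in ``groups`` are counted.
    ``level`` is ``molecule``, ``ATC-2`` (e.g. A10), or ``ATC-main`` (the
    anatomical letter).  Drugs used by nobody in the tested population are
    excluded.  Records are sorted by p, with a Bonferroni-significance
    column over the scanned codes.
    """
    if level not in ("molecule", "ATC-2", "ATC-main"):
        raise ValueError(f"unknown level {level!r}")
    population = set(groups.index)
    if not population:
        raise ValueError("empty group table")
    counts = groups.value_counts()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError("need at least two nonempty groups")

    if level == "molecule":
        codes = sorted(set(med_table.records["molecule"]))
        lookup = "molecule"
    else:
        width = 3 if level == "ATC-2" else 1
        codes = sorted(
            {
                c[:width]
                for cs in med_table.records["atc_codes"]
                for c in cs.split(";")
            }
        )
        lookup = "atc"

    rows = []
    for code in codes:
        users = med_table.users(code, "molecule" if lookup == "molecule" else "atc")
        users &= population
        if not users:
            continue
        for g in counts.index:
            in_group = set(groups.index[groups == g])
            a = len(users & in_group)
            b = len(in_group) - a
            c = len(users - in_group)
            d = len(population) - len(in_group) - c
            orr, p = fisher_exact_2x2([[a, b], [c, d]])
            rows.append(
                {
                    "code": code,
                    "level": level,
                    "group": g,
                    "users_in_group": a,
                    "nonusers_in_group": b,
                    "users_out_group": c,
                    "nonusers_out_group": d,
                    "odds_ratio": orr,
                    "p": p,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "code", "level", "group", "users_in_group", "nonusers_in_group",
            "users_out_group", "nonusers_out_group", "odds_ratio", "p",
        ],
    )
    if len(out):
        threshold = bonferroni_threshold(alpha, out["code"].nunique())
        out["bonferroni_significant"] = out["p"] < threshold
        out.attrs["bonferroni_threshold"] = threshold
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
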