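"""BCI-illiteracy categorization and rates from a decoding-accuracy table.

Subjects are called *literate* in a paradigm when their decoding accuracy
reaches a threshold — 70% for motor imagery (judged on the conventional
CSP decoder) and 90% for the ERP and SSVEP paradigms — in every recorded
session.  Accuracy exactly equal to the threshold counts as literate; this
boundary rule changes headline rates, so it is applied explicitly and
tested.  Categories:

* universally literate  — above threshold in all three paradigms,
* partially literate    — in one or two,
* universally illiterate — in none.

Per-paradigm illiteracy *rates* are computed per session (fraction of
subjects strictly below threshold), plus their mean across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PARADIGMS",
    "LiteracyThresholds",
    "validate_accuracy_table",
    "categorize_subject",
    "categorize_all",
    "illiteracy_rates",
    "paradigm_correlations",
]

PARADIGMS = ("MI", "ERP", "SSVEP")
CATEGORIES = ("universally_literate", "partially_literate", "universally_illiterate")

TABLE_COLUMNS = ["subject", "session", "paradigm", "method", "accuracy"]


@dataclass(frozen=True)
class LiteracyThresholds:
    mi: float = 0.70
    erp: float = 0.90
    ssvep: float = 0.90
    mi_criterion_method: str = "CSP"

    def __post_init__(self):
        for v in (self.mi, self.erp, self.ssvep):
            if not 0.0 < v < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")

    def for_paradigm(self, paradigm: str) -> float:
        return {"MI": self.mi, "ERP": self.erp, "SSVEP": self.ssvep}[paradigm]


def validate_accuracy_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants of a (subject, session, paradigm, method,
    accuracy) table; returns a normalized copy."""
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"accuracy table lacks columns {sorted(missing)}")
    t = table[TABLE_COLUMNS].copy()
    t["paradigm"] = t["paradigm"].str.upper()
    if not t["paradigm"].isin(PARADIGMS).all():
        bad = sorted(set(t["paradigm"]) - set(PARADIGMS))
        raise ValueError(f"unknown paradigm(s) {bad}")
    if ((t["accuracy"] < 0) | (t["accuracy"] > 1)).any():
        raise ValueError("accuracies must lie in [0, 1]")
    key = ["subject", "session", "paradigm", "method"]
    if t.duplicated(key).any():
        raise ValueError("duplicate (subject, session, paradigm, method) rows")
    return t


def _criterion_rows(t: pd.DataFrame, th: LiteracyThresholds) -> pd.DataFrame:
    """Rows used for literacy decisions: the MI criterion method plus all
    ERP/SSVEP rows."""
    mi = t[(t.paradigm == "MI") & (t.method == th.mi_criterion_method)]
    other = t[t.paradigm != "MI"]
    return pd.concat([mi, other], ignore_index=True)


def categorize_subject(
    table: pd.DataFrame, th: LiteracyThresholds, subject
) -> tuple[str, dict[str, bool]]:
    """Literacy category and per-paradigm literate flags for one subject.

    A paradigm is literate iff accuracy >= threshold in *all* sessions
    present for that subject.
    """
    t = _criterion_rows(validate_accuracy_table(table), th)
    rows = t[t.subject == subject]
    flags = {}
    for paradigm in PARADIGMS:
        sub = rows[rows.paradigm == paradigm]
        if sub.empty:
            raise ValueError(f"subject {subject!r} has no {paradigm} accuracy"
                             + (f" for method {th.mi_criterion_method}" if paradigm == "MI" else ""))
        flags[paradigm] = bool((sub.accuracy >= th.for_paradigm(paradigm)).all())
    n = sum(flags.values())
    category = CATEGORIES[0] if n == 3 else (CATEGORIES[2] if n == 0 else CATEGORIES[1])
    return category, flags


def categorize_all(table: pd.DataFrame, th: LiteracyThresholds = LiteracyThresholds()) -> pd.DataFrame:
    """Per-subject categories as a DataFrame (subject, MI/ERP/SSVEP flags,
    category)."""
    t = validate_accuracy_table(table)
    records = []
    for subject in sorted(t.subject.unique()):
        category, flags = categorize_subject(t, th, subject)
        records.append({"subject": subject, **{f"{p}_literate": flags[p] for p in PARADIGMS},
                        "category": category})
    return pd.DataFrame(records)


def illiteracy_rates(
    table: pd.DataFrame, th: LiteracyThresholds = LiteracyThresholds()
) -> dict:
    """Per-paradigm, per-session illiteracy rates plus category counts.

    The rate is the fraction of subjects with accuracy strictly below the
    paradigm threshold in that session (MI judged on the criterion method).
    """
    t = _criterion_rows(validate_accuracy_table(table), th)
    if t.empty:
        raise ValueError("accuracy table is empty")
    rates: dict[str, dict] = {}
    for paradigm in PARADIGMS:
        sub = t[t.paradigm == paradigm]
        per_session = {}
        for session in sorted(sub.session.unique()):
            s = sub[sub.session == session]
            per_session[str(session)] = float(
                (s.accuracy < th.for_paradigm(paradigm)).mean()
            )
        rates[paradigm] = {
            "per_session": per_session,
            "mean": float(np.mean(list(per_session.values()))) if per_session else float("nan"),
        }
    cats = categorize_all(table, th)
    counts = {c: int((cats.category == c).sum()) for c in CATEGORIES}
    counts["n_subjects"] = int(len(cats))
    return {"thresholds": {"MI": th.mi, "ERP": th.erp, "SSVEP": th.ssvep},
            "rates": rates, "categories": counts}


def paradigm_correlations(table: pd.DataFrame,
                          th: LiteracyThresholds = LiteracyThresholds()) -> dict[str, float]:
    """Pearson r between paradigms on session-averaged per-subject accuracy.

    Returns NaN for a pair whenever one side has zero variance.
    """
    t = _criterion_rows(validate_accuracy_table(table), th)
    mean_acc = (
        t.groupby(["subject", "paradigm"]).accuracy.mean().unstack("paradigm")
    )
    if len(mean_acc) < 3:
        raise ValueError("need at least 3 subjects for correlations")
    out = {}
    for a, b in (("MI", "ERP"), ("MI", "SSVEP"), ("SSVEP", "ERP")):
        x, y = mean_acc[a].to_numpy(), mean_acc[b].to_numpy()
        # tolerance guard: averaging can leave ~1e-16 jitter on constant input
        if np.std(x) <= 1e-12 or np.std(y) <= 1e-12:
            out[f"{a}-{b}"] = float("nan")
        else:
            out[f"{a}-{b}"] = float(stats.pearsonr(x, y)[0])
    return out
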