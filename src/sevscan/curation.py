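"""Sanitation of clinical mutation tables and severity labelling.

Clinical registries of factor VIII missense variants report measured
clotting activity (FVIII:C, % of normal) in messy free text: censored
values (">5", "<1"), ranges ("10-24"), and ambiguous entries ("0 to 2").
This module normalises activity strings deterministically, applies the
registry-specific row filters (two dialects: an EAHAD-style registry and
a CHAMP-style registry), maps activity to the clinical severity bands
(severe < 1%, moderate 1-5%, mild 5-40% FVIII:C) and produces the binary
labels (severe vs mild/moderate) used for model training.  Every rejected
row is attributed to exactly one named rule so the tally always accounts
for the whole input.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "MutationRecord",
    "normalize_activity",
    "sanitize_records",
    "label_severity",
    "binarize_labels",
    "DIALECTS",
    "SEVERITY_BANDS",
]

AA_CODES = set("ACDEFGHIKLMNPQRSTVWY")
STOP_CODES = {"*", "X", "TER", "STOP"}

# Censored activity strings with a fixed substitution (registry policy).
SENTINEL_MAP = {">5": 5.0, "<10": 10.0, "<11": 11.0, "<1": 0.0}

# Half-open severity bands on % FVIII:C.  The clinical definitions overlap
# at the boundaries ("1-5", "5-40"); the bands used here are [0,1) severe,
# [1,5) moderate, [5,40] mild, (40,100] non-hemophilic.
SEVERITY_BANDS = {"severe": (0.0, 1.0), "moderate": (1.0, 5.0), "mild": (5.0, 40.0)}

_RANGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*[-–—]\s*(\d+(?:\.\d+)?)\s*$")
_NUMBER_RE = re.compile(r"^\s*\d+(?:\.\d+)?\s*$")


@dataclass
class MutationRecord:
    """One curated clinical report of a single-residue substitution."""

    position: int  # mature-protein numbering
    wt_aa: str
    mut_aa: str
    activity_raw: str = ""
    activity: float | None = None  # % FVIII:C in [0, 100]
    severity: str | None = None  # mild | moderate | severe
    inhibitor_info: bool = False
    source: str = "other"


def normalize_activity(raw) -> tuple[float | None, str | None]:
    """Map a verbatim activity cell to a % FVIII:C value or a reject reason.

    Returns ``(value, None)`` on success or ``(None, reason)`` with reason
    one of ``missing``, ``ambiguous``, ``unparseable``.  Rules, applied in
    order: plain numbers pass through; the fixed sentinel substitutions
    ">5"->5, "<10"->10, "<11"->11, "<1"->0; dash ranges "a-b" become the
    arithmetic mean; worded or censored ranges ("0 to 2", "<1 to 2") and
    any other censored value ("<2") are ambiguous; anything else is
    unparseable.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None, "missing"
    s = str(raw).strip().replace("%", "").strip()
    if not s or s.lower() in {"na", "n/a", "nan", "-", "?"}:
        return None, "missing"
    if _NUMBER_RE.match(s):
        return float(s), None
    compact = s.replace(" ", "")
    if compact in SENTINEL_MAP:
        return SENTINEL_MAP[compact], None
    m = _RANGE_RE.match(s)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        return (lo + hi) / 2.0, None
    if re.search(r"\bto\b", s, flags=re.IGNORECASE) or compact.startswith(("<", ">")):
        return None, "ambiguous"
    return None, "unparseable"


def label_severity(activity: float) -> str:
    """Ternary severity from % FVIII:C.

    [0,1) -> severe; [1,5) -> moderate; [5,40] -> mild; activity in
    (40,100] is labelled ``non_hemophilic`` (excluded from modelling).
    """
    if activity < 0:
        raise ValueError(f"negative activity {activity}")
    if activity > 100:
        raise ValueError(f"activity {activity} exceeds 100%")
    if activity < 1:
        return "severe"
    if activity < 5:
        return "moderate"
    if activity <= 40:
        return "mild"
    return "non_hemophilic"


AMBIGUOUS_SEVERITY_RE = re.compile(r"/|\bor\b", flags=re.IGNORECASE)

#: Column maps for the two supported registry dialects.
DIALECTS = {
    "EAHAD": {
        "position": "position",
        "wt_aa": "wt_aa",
        "mut_aa": "mut_aa",
        "activity": "fviii_c_1st",
        "activity_2nd": "fviii_c_2st",
        "severity": "severity",
        "inhibitor": "inhibitor",
        "variant_type": "type",
        "effect": "effect",
    },
    "CHAMP": {
        "position": "position",
        "wt_aa": "wt_aa",
        "mut_aa": "mut_aa",
        "activity": "fviii_c",
        "severity": "severity",
        "effect": "effect",
    },
}


@dataclass
class SanitationResult:
    kept: pd.DataFrame
    tally: dict[str, int] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return sum(self.tally.values())


def _norm_aa(code) -> str:
    s = str(code).strip().upper()
    return s


def sanitize_records(
    records: pd.DataFrame,
    source_dialect: str = "EAHAD",
    mature_length: int = 2332,
    columns: dict[str, str] | None = None,
) -> SanitationResult:
    """Apply the registry sanitation rules; every rejection hits one rule.

    Rules run per row, in order; the first matching rule claims the row.
    EAHAD-style order: scope filters (missense point variants only, when
    the type/effect columns exist), position outside the mature protein
    [1, mature_length], stop codon, activity > 100, unresolvable activity
    strings, rows without activity and without inhibitor information,
    discrepancy between the first- and second-stage activity columns
    (values implying different severity bands), ambiguous severity labels
    ("mild/moderate").  CHAMP-style adds duplicate removal on
    (position, wt, mut).  Output rows carry normalised ``activity`` and,
    where derivable, ``severity``.
    """
    if source_dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {source_dialect!r}")
    cols = dict(DIALECTS[source_dialect])
    if columns:
        cols.update(columns)
    for required in ("position", "wt_aa", "mut_aa"):
        if cols[required] not in records.columns:
            raise ValueError(
                f"dialect {source_dialect}: missing mandatory column "
                f"{cols[required]!r}"
            )

    tally: dict[str, int] = {}
    kept_rows = []
    seen: set[tuple] = set()

    def reject(rule: str) -> None:
        tally[rule] = tally.get(rule, 0) + 1

    def resolve(role: str, canonical: str | None = None) -> str | None:
        # fall back to the canonical curated-output column name so that
        # sanitised output can be re-sanitised unchanged (idempotence)
        name = cols.get(role)
        if name and name in records.columns:
            return name
        if canonical and canonical in records.columns:
            return canonical
        return name

    act_col = resolve("activity", "activity")
    act2_col = cols.get("activity_2nd")
    sev_col = resolve("severity", "severity")
    inh_col = cols.get("inhibitor")
    type_col = cols.get("variant_type")
    eff_col = cols.get("effect")

    for _, row in records.iterrows():
        if type_col and type_col in records.columns:
            vtype = str(row[type_col]).strip().lower()
            if vtype not in {"point", "polymorphism", "nan", ""}:
                reject("not_point_variant")
                continue
        if eff_col and eff_col in records.columns:
            eff = str(row[eff_col]).strip().lower()
            if eff not in {"missense", "nan", ""}:
                reject("not_missense")
                continue

        wt = _norm_aa(row[cols["wt_aa"]])
        mut = _norm_aa(row[cols["mut_aa"]])
        if mut in STOP_CODES:
            reject("stop_codon")
            continue
        if wt not in AA_CODES or mut not in AA_CODES:
            reject("invalid_residue_code")
            continue
        if wt == mut:
            reject("synonymous")
            continue

        try:
            pos = int(row[cols["position"]])
        except (TypeError, ValueError):
            reject("invalid_position")
            continue
        if pos < 1 or pos > mature_length:
            reject("outside_mature_protein")
            continue

        raw = row[act_col] if act_col and act_col in records.columns else None
        value, reason = normalize_activity(raw)
        severity = None

        if value is not None and value > 100:
            reject("activity_over_100")
            continue
        if reason == "ambiguous":
            reject("ambiguous_activity")
            continue
        if reason == "unparseable":
            reject("unparseable_activity")
            continue
        if reason == "missing":
            has_inhibitor = (
                inh_col is not None
                and inh_col in records.columns
                and str(row[inh_col]).strip().lower() not in {"", "nan", "na"}
            )
            reported = (
                sev_col is not None
                and sev_col in records.columns
                and str(row[sev_col]).strip().lower() not in {"", "nan", "na"}
            )
            if not has_inhibitor and not reported:
                reject("no_activity_no_inhibitor")
                continue

        if (
            value is not None
            and act2_col is not None
            and act2_col in records.columns
        ):
            value2, reason2 = normalize_activity(row[act2_col])
            if value2 is not None and value2 <= 100:
                if label_severity(value) != label_severity(value2):
                    reject("stage_discrepancy")
                    continue

        sev_raw = ""
        if sev_col and sev_col in records.columns:
            sev_raw = str(row[sev_col]).strip().lower()
            if sev_raw in {"nan", "na"}:
                sev_raw = ""
        if sev_raw and AMBIGUOUS_SEVERITY_RE.search(sev_raw):
            reject("ambiguous_severity")
            continue
        if value is not None:
            severity = label_severity(value)
        elif sev_raw in {"mild", "moderate", "severe"}:
            severity = sev_raw

        key = (pos, wt, mut)
        if source_dialect == "CHAMP":
            if key in seen:
                reject("duplicate")
                continue
            seen.add(key)

        raw_display = "" if raw is None else str(raw)
        if "activity_raw" in records.columns:
            prior = str(row["activity_raw"]).strip()
            if prior and prior.lower() != "nan":
                raw_display = prior
        kept_rows.append(
            {
                "position": pos,
                "wt_aa": wt,
                "mut_aa": mut,
                "activity_raw": raw_display,
                "activity": value,
                "severity": severity,
                "source": source_dialect,
            }
        )

    kept = pd.DataFrame(
        kept_rows,
        columns=["position", "wt_aa", "mut_aa", "activity_raw", "activity",
                 "severity", "source"],
    )
    return SanitationResult(kept=kept, tally=tally)


def binarize_labels(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Binary labels: severe (1) vs merged mild/moderate (0).

    Rows whose severity is missing or non-hemophilic are excluded and
    tallied.  Returns the labelled frame (with a ``label`` column) and the
    class/exclusion counts.
    """
    counts = {"severe": 0, "mild/moderate": 0, "excluded_missing_severity": 0,
              "excluded_non_hemophilic": 0}
    if records.empty:
        out = records.copy()
        out["label"] = pd.Series(dtype=int)
        return out, counts
    rows = []
    for _, row in records.iterrows():
        sev = row.get("severity")
        if sev is None or (isinstance(sev, float) and pd.isna(sev)):
            counts["excluded_missing_severity"] += 1
            continue
        if sev == "non_hemophilic":
            counts["excluded_non_hemophilic"] += 1
            continue
        label = 1 if sev == "severe" else 0
        counts["severe" if label else "mild/moderate"] += 1
        r = dict(row)
        r["label"] = label
        rows.append(r)
    out = pd.DataFrame(rows)
    if rows and len({r["label"] for r in rows}) == 1:
        warnings.warn("single-class label set after binarisation", stacklevel=2)
    return out, counts
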