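"""Loader for the published pediatric lipoprotein/HOMA-IR cohort table.

The study's supplementary spreadsheet (841 children; HOMA-IR, 26
NMR-predicted lipoprotein features, age, sex, three adiposity measures, and
23 physical-activity intensity-bin variables) is not redistributed with the
package; place it at ``data/table_s1.xlsx`` (or pass an explicit path). The
loader matches columns against the expected variable set after normalizing
punctuation and case; mismatches are reported, never guessed.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .data import DataTable
from .errors import ConfigurationError

#: 26 lipoprotein features: class/subclass concentrations and average sizes.
LIPOPROTEINS = [
    "TC", "TG", "CM", "VLDL", "LDL", "HDL",
    "CM-1", "CM-2",
    "VLDL-L1", "VLDL-L2", "VLDL-L3", "VLDL-M", "VLDL-S",
    "LDL-L", "LDL-M", "LDL-S", "LDL-VS",
    "HDL-VL1", "HDL-VL2", "HDL-L", "HDL-M", "HDL-S", "HDL-VS",
    "VLDL size", "LDL size", "HDL size",
]
ADIPOSITY = ["BMI", "WC/H", "skinfold"]
OUTCOME = "HOMA-IR"
N_PA_BINS = 23

DEFAULT_PATH = Path("data") / "table_s1.xlsx"


def _norm(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


def load_study_table(path=None) -> DataTable:
    """Read the supplementary cohort table and attach study roles.

    Raises :class:`ConfigurationError` listing every expected variable that
    could not be matched, or if the physical-activity intensity bins cannot
    be identified unambiguously.
    """
    path = Path(path) if path is not None else DEFAULT_PATH
    if not path.exists():
        raise ConfigurationError(
            f"study table not found at {path}; download the supplementary "
            "cohort spreadsheet and place it there"
        )
    frame = pd.read_excel(path, sheet_name=0, index_col=0, engine="openpyxl")
    frame.columns = [str(c).strip() for c in frame.columns]
    by_norm: dict[str, str] = {}
    for c in frame.columns:
        by_norm.setdefault(_norm(c), c)

    def match(expected: str) -> str | None:
        return by_norm.get(_norm(expected))

    missing: list[str] = []
    resolved: dict[str, str] = {}
    for name in [OUTCOME, "age", "sex", *ADIPOSITY, *LIPOPROTEINS]:
        col = match(name)
        if col is None:
            missing.append(name)
        else:
            resolved[name] = col

    # PA bins: columns whose names look like cpm intensity ranges
    pa_pattern = re.compile(r"(\d{1,2}500|\d+00)\s*[-–]\s*\d+|>=?\s*10,?000|pa", re.I)
    claimed = set(resolved.values())
    pa_cols = [c for c in frame.columns if c not in claimed and pa_pattern.search(c)]
    if len(pa_cols) != N_PA_BINS:
        missing.append(f"{N_PA_BINS} PA intensity bins (found {len(pa_cols)})")
    if missing:
        raise ConfigurationError(
            "study table dialect mismatch; unmatched variables: " + ", ".join(missing)
        )

    keep = [resolved[OUTCOME], resolved["age"], resolved["sex"]]
    keep += [resolved[a] for a in ADIPOSITY]
    keep += pa_cols
    keep += [resolved[l] for l in LIPOPROTEINS]
    sub = frame[keep].astype(float)

    roles = {resolved[OUTCOME]: "outcome", resolved["age"]: "covariate",
             resolved["sex"]: "covariate"}
    groups = {resolved["age"]: "age", resolved["sex"]: "sex"}
    for a in ADIPOSITY:
        roles[resolved[a]] = "covariate"
        groups[resolved[a]] = "adiposity"
    for c in pa_cols:
        roles[c] = "covariate"
        groups[c] = "pa"
    for l in LIPOPROTEINS:
        roles[resolved[l]] = "explanatory"

    return DataTable(frame=sub, roles=roles, groups=groups,
                     group_order=["age", "sex", "adiposity", "pa"])


def pretreat_study(table: DataTable):
    """Study pretreatment: log everything except age and sex, then autoscale."""
    from .data import pretreat

    age = next(c for c, g in table.groups.items() if g == "age")
    sex = next(c for c, g in table.groups.items() if g == "sex")
    return pretreat(table, log_exempt=[age, sex], offset_policy="auto")
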