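"""Data container, variable-role bookkeeping, and pretreatment.

The analyses in this package operate on a complete-case samples x variables
table in which every variable plays one of three roles:

* ``outcome`` -- the single response variable (e.g. HOMA-IR),
* ``explanatory`` -- the multicollinear block whose association pattern with
  the outcome is of interest (e.g. 26 NMR-derived lipoprotein features),
* ``covariate`` -- variables whose influence is to be assessed and projected
  out; every covariate belongs to a named, ordered group (e.g. ``age``,
  ``sex``, ``adiposity``, ``pa``).

Pretreatment follows common chemometric practice: log-transform of
right-skewed positive variables (binary and narrow-range variables exempt),
then autoscaling (mean-centering and scaling to unit sample variance).
A :class:`PreprocessState` records the exact transform so it can be replayed
or inverted.
"""

from __future__ import annotations

import fnmatch
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import (
    CompleteCaseError,
    ConfigurationError,
    DegenerateError,
    DomainError,
)

ROLES = ("outcome", "explanatory", "covariate")

#: Default log offset for variables that may contain exact zeros (e.g. minutes
#: per day spent in a high-intensity activity bin): one minute expressed as a
#: fraction of a day.
DEFAULT_ZERO_OFFSET = 1.0 / 1440.0


@dataclass
class DataTable:
    """Named samples x variables matrix with role and group labels.

    Parameters
    ----------
    frame:
        ``pandas.DataFrame`` of float values, index = sample ids,
        columns = variable names.
    roles:
        Mapping variable name -> role (one of ``outcome``, ``explanatory``,
        ``covariate``).
    groups:
        Mapping variable name -> covariate-group label. Every covariate must
        have a group; non-covariates must not.
    group_order:
        The order in which covariate groups are adjusted for.
    """

    frame: pd.DataFrame
    roles: dict[str, str]
    groups: dict[str, str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        cols = list(self.frame.columns)
        for name, role in self.roles.items():
            if role not in ROLES:
                raise ConfigurationError(f"unknown role {role!r} for {name!r}")
            if name not in cols:
                raise ConfigurationError(f"role assigned to absent column {name!r}")
        missing = [c for c in cols if c not in self.roles]
        if missing:
            raise ConfigurationError(f"columns without a role: {missing}")
        outcomes = [c for c in cols if self.roles[c] == "outcome"]
        if len(outcomes) != 1:
            raise ConfigurationError(
                f"exactly one outcome required, got {len(outcomes)}: {outcomes}"
            )
        for name in cols:
            is_cov = self.roles[name] == "covariate"
            has_group = name in self.groups
            if is_cov and not has_group:
                raise ConfigurationError(f"covariate {name!r} has no group label")
            if not is_cov and has_group:
                raise ConfigurationError(f"non-covariate {name!r} has a group label")
        if self.frame.isna().any().any():
            bad = self.frame.index[self.frame.isna().any(axis=1)].tolist()
            raise CompleteCaseError(
                f"{len(bad)} sample(s) have missing values: {bad[:10]}", samples=bad
            )
        seen_groups = {g for g in self.groups.values()}
        if not self.group_order:
            # preserve first-appearance order of the covariate columns
            order: list[str] = []
            for c in cols:
                g = self.groups.get(c)
                if g is not None and g not in order:
                    order.append(g)
            self.group_order = order
        unknown = [g for g in self.group_order if g not in seen_groups]
        if unknown:
            raise ConfigurationError(f"group_order names unknown groups: {unknown}")

    # -- accessors --------------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    @property
    def variable_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_samples(self) -> int:
        return self.frame.shape[0]

    @property
    def outcome_name(self) -> str:
        return next(c for c in self.frame.columns if self.roles[c] == "outcome")

    @property
    def explanatory_names(self) -> list[str]:
        return [c for c in self.frame.columns if self.roles[c] == "explanatory"]

    def group_members(self, group: str) -> list[str]:
        members = [c for c in self.frame.columns if self.groups.get(c) == group]
        if not members:
            raise ConfigurationError(f"no covariates in group {group!r}")
        return members

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)

    def with_frame(self, frame: pd.DataFrame) -> "DataTable":
        return replace(self, frame=frame)


@dataclass
class PreprocessState:
    """Replayable record of the pretreatment applied to each variable."""

    log_applied: dict[str, bool]
    offset: dict[str, float]
    mean: dict[str, float]
    scale: dict[str, float]

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for name in frame.columns:
            v = frame[name].to_numpy(dtype=float)
            if self.log_applied[name]:
                shifted = v + self.offset[name]
                if np.any(shifted <= 0):
                    i = int(np.argmax(shifted <= 0))
                    raise DomainError(
                        f"variable {name!r}, sample {frame.index[i]!r}: "
                        f"value {v[i]} not positive after offset {self.offset[name]}"
                    )
                v = np.log(shifted)
            out[name] = (v - self.mean[name]) / self.scale[name]
        return pd.DataFrame(out, index=frame.index)

    def inverse_transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for name in frame.columns:
            v = frame[name].to_numpy(dtype=float) * self.scale[name] + self.mean[name]
            if self.log_applied[name]:
                v = np.exp(v) - self.offset[name]
            out[name] = v
        return pd.DataFrame(out, index=frame.index)


def pretreat(
    table: DataTable,
    log_exempt: list[str] | None = None,
    offset_policy: float | dict[str, float] | str = "auto",
) -> tuple[DataTable, PreprocessState]:
    """Log-transform (non-exempt variables), mean-center and autoscale.

    Parameters
    ----------
    table:
        Complete-case input table on the original measurement scale.
    log_exempt:
        Variables excluded from the log transform (typically age and a binary
        sex indicator). They are still centered and scaled.
    offset_policy:
        How to handle zeros (and values below recording resolution) before
        the log. ``"auto"`` (default) adds :data:`DEFAULT_ZERO_OFFSET` to any
        non-exempt variable containing a value below that constant; a float
        does the same with the given offset; a dict gives explicit
        per-variable offsets. Values still non-positive after the offset
        raise a :class:`~covproj.errors.DomainError`.

    Returns
    -------
    (DataTable, PreprocessState)
        The pretreated table (each column mean 0, sample variance 1) and the
        state needed to replay or invert the transform.
    """
    log_exempt = list(log_exempt or [])
    for name in log_exempt:
        if name not in table.frame.columns:
            raise ConfigurationError(f"log_exempt names absent column {name!r}")

    log_applied: dict[str, bool] = {}
    offsets: dict[str, float] = {}
    means: dict[str, float] = {}
    scales: dict[str, float] = {}

    for name in table.frame.columns:
        v = table.column(name)
        do_log = name not in log_exempt
        off = 0.0
        if do_log:
            if isinstance(offset_policy, dict):
                off = float(offset_policy.get(name, 0.0))
            elif offset_policy == "auto":
                off = DEFAULT_ZERO_OFFSET if np.any(v < DEFAULT_ZERO_OFFSET) else 0.0
            else:
                off = float(offset_policy) if np.any(v < float(offset_policy)) else 0.0
            shifted = v + off
            if np.any(shifted <= 0):
                i = int(np.argmax(shifted <= 0))
                raise DomainError(
                    f"variable {name!r}, sample {table.frame.index[i]!r}: "
                    f"value {v[i]} is not positive after offset {off}; "
                    "add it to log_exempt or set an offset"
                )
            v = np.log(shifted)
        mu = float(np.mean(v))
        sd = float(np.std(v, ddof=1))
        if not math.isfinite(sd) or sd <= 0:
            raise DegenerateError(f"variable {name!r} has zero variance; cannot scale")
        log_applied[name] = do_log
        offsets[name] = off
        means[name] = mu
        scales[name] = sd

    state = PreprocessState(log_applied, offsets, means, scales)
    return table.with_frame(state.transform(table.frame)), state


def standardize_vector(v: np.ndarray) -> np.ndarray:
    """Center a vector and scale it to unit sample variance.

    The same sum-of-squares convention as :func:`pretreat` (``ddof=1``), so a
    standardized vector has sum of squares ``n - 1``.
    """
    v = np.asarray(v, dtype=float)
    sd = float(np.std(v, ddof=1))
    if not math.isfinite(sd) or sd <= 0:
        raise DegenerateError("cannot standardize a zero-variance vector")
    return (v - float(np.mean(v))) / sd


# ---------------------------------------------------------------------------
# loading


def parse_role_config(path_or_mapping) -> dict:
    """Read a role configuration (YAML key-value file or mapping).

    Expected keys::

        outcome: HOMA-IR
        explanatory: ["LP-*"]          # names or glob patterns
        covariate_groups:              # ordered
          age: [age]
          sex: [sex]
          adiposity: [BMI, WC_H, skinfold]
          pa: ["PA-*"]
    """
    if isinstance(path_or_mapping, dict):
        cfg = path_or_mapping
    else:
        with open(path_or_mapping) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "outcome" not in cfg:
        raise ConfigurationError("role config must be a mapping with an 'outcome' key")
    return cfg


def _expand(patterns, columns: list[str], what: str) -> list[str]:
    if isinstance(patterns, str):
        patterns = [patterns]
    out: list[str] = []
    for pat in patterns:
        if pat in columns:
            hits = [pat]
        else:
            hits = [c for c in columns if fnmatch.fnmatchcase(c, pat)]
        if not hits:
            raise ConfigurationError(f"{what} pattern {pat!r} matches no column")
        out.extend(h for h in hits if h not in out)
    return out


def load_table(path, format: str | None = None, role_config=None) -> DataTable:
    """Load a samples x variables table and attach roles.

    The first column holds sample ids; the header row holds variable names.
    ``format`` is inferred from the file suffix when omitted
    (csv / tsv / xlsx; XLSX reads the first sheet).
    """
    path = str(path)
    if format is None:
        suffix = path.rsplit(".", 1)[-1].lower()
        format = {"csv": "csv", "tsv": "tsv", "txt": "tsv", "xlsx": "xlsx"}.get(suffix)
        if format is None:
            raise ConfigurationError(f"cannot infer format from {path!r}")
    if format == "csv":
        frame = pd.read_csv(path, index_col=0)
    elif format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "xlsx":
        frame = pd.read_excel(path, sheet_name=0, index_col=0, engine="openpyxl")
    else:
        raise ConfigurationError(f"unsupported format {format!r}")

    cfg = parse_role_config(role_config)
    columns = [str(c) for c in frame.columns]
    frame.columns = columns

    outcome = cfg["outcome"]
    if outcome not in columns:
        raise ConfigurationError(f"outcome column {outcome!r} not in file")

    groups_cfg = cfg.get("covariate_groups", {}) or {}
    roles: dict[str, str] = {outcome: "outcome"}
    groups: dict[str, str] = {}
    group_order: list[str] = []
    for gname, members in groups_cfg.items():
        group_order.append(str(gname))
        for m in _expand(members, columns, f"covariate group {gname!r}"):
            if m in roles:
                raise ConfigurationError(f"column {m!r} assigned twice")
            roles[m] = "covariate"
            groups[m] = str(gname)

    expl_cfg = cfg.get("explanatory")
    if expl_cfg is None:
        expl = [c for c in columns if c not in roles]
    else:
        expl = _expand(expl_cfg, columns, "explanatory")
    for m in expl:
        if m in roles:
            raise ConfigurationError(f"column {m!r} assigned twice")
        roles[m] = "explanatory"

    keep = [c for c in columns if c in roles]
    frame = frame[keep].astype(float)
    return DataTable(frame=frame, roles=roles, groups=groups, group_order=group_order)
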