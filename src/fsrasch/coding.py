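"""Binary coding of the raw 18-item household food-security survey.

The questionnaire has three response classes:

* frequency items E1-E6 ("often true" / "sometimes true" / "never true"):
  often or sometimes are affirmative (1), never is negative (0);
* yes/no items E7, E9-E12, E14, E15, E17, E18: yes -> 1, no -> 0; a
  "don't know" is coded 0 by default (configurable to missing);
* how-often follow-ups E8, E13, E16 ("almost every month" / "some months" /
  "only 1 or 2 months"): almost-every-month or some-months -> 1, only one or
  two months -> 0; a follow-up whose gate question (E7, E12, E15) was
  answered negatively is not applicable and is coded 0.

Coding is idempotent: cells that are already 0/1 pass through unchanged, so a
binary matrix round-trips through :func:`build_binary_matrix`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CodingError, UserInputError

__all__ = [
    "BinaryResponseMatrix",
    "code_frequency_item",
    "code_yes_no",
    "code_how_often",
    "build_binary_matrix",
    "FREQUENCY_ITEMS",
    "YES_NO_ITEMS",
    "HOW_OFTEN_ITEMS",
    "GATE_OF",
    "DEFAULT_ITEM_IDS",
]

DEFAULT_ITEM_IDS = tuple(f"E{i}" for i in range(1, 19))

FREQUENCY_ITEMS = ("E1", "E2", "E3", "E4", "E5", "E6")
HOW_OFTEN_ITEMS = ("E8", "E13", "E16")
#: follow-up item -> its gate question
GATE_OF = {"E8": "E7", "E13": "E12", "E16": "E15"}
YES_NO_ITEMS = tuple(
    i for i in DEFAULT_ITEM_IDS if i not in FREQUENCY_ITEMS + HOW_OFTEN_ITEMS
)

MISSING = object()  #: sentinel for a missing cell under the as_missing policy

_MISSING_CODES = {"", "na", "nan", "none", "missing", "."}


def _normalize(level) -> str | int | None:
    """Canonicalize a raw level: lowercase, squeeze separators; 0/1 pass through.

    Returns ``None`` for recognised missing codes.
    """
    if level is None or (isinstance(level, float) and np.isnan(level)):
        return None
    if isinstance(level, (int, np.integer)) and level in (0, 1):
        return int(level)
    if isinstance(level, (float, np.floating)) and level in (0.0, 1.0):
        return int(level)
    s = str(level).strip().lower()
    if s in _MISSING_CODES:
        return None
    if s in ("0", "1"):
        return int(s)
    s = s.replace("'", "")  # don't know -> dont know
    s = re.sub(r"[\s\-/]+", "_", s)
    s = re.sub(r"[^a-z0-9_]", "", s)
    return s


_FREQ_MAP = {"often_true": 1, "sometimes_true": 1, "never_true": 0,
             "often": 1, "sometimes": 1, "never": 0}
_YN_MAP = {"yes": 1, "no": 0, "y": 1, "n": 0}
_DK = {"dont_know", "do_not_know", "dk"}
_HOW_MAP = {
    "almost_every_month": 1,
    "some_months": 1,
    "one_or_two_months": 0,
    "only_1_or_2_months": 0,
    "only_one_or_two_months": 0,
    "1_or_2_months": 0,
    "not_applicable": 0,
}


def _err(level, item=None, row=None):
    where = ""
    if row is not None or item is not None:
        where = f" (row {row!r}, item {item!r})"
    return CodingError(f"unknown response level {level!r}{where}")


def code_frequency_item(level, *, item=None, row=None) -> int:
    """Code an often/sometimes/never level: often or sometimes -> 1, never -> 0."""
    v = _normalize(level)
    if isinstance(v, int):
        return v
    if v in _FREQ_MAP:
        return _FREQ_MAP[v]
    raise _err(level, item, row)


def code_yes_no(level, dk_policy: str = "as_negative", *, item=None, row=None):
    """Code a yes/no/don't-know level.

    yes -> 1, no -> 0; "don't know" -> 0 under ``as_negative`` (default) or
    the :data:`MISSING` marker under ``as_missing``.
    """
    if dk_policy not in ("as_negative", "as_missing"):
        raise UserInputError(f"dk_policy must be as_negative or as_missing, got {dk_policy!r}")
    v = _normalize(level)
    if isinstance(v, int):
        return v
    if v in _YN_MAP:
        return _YN_MAP[v]
    if v in _DK:
        return 0 if dk_policy == "as_negative" else MISSING
    raise _err(level, item, row)


def code_how_often(level, *, item=None, row=None) -> int:
    """Code a how-often follow-up level.

    almost-every-month and some-months are affirmative; only-1-or-2-months is
    negative, as is not-applicable (a skipped follow-up cannot be affirmed).
    """
    v = _normalize(level)
    if isinstance(v, int):
        return v
    if v in _HOW_MAP:
        return _HOW_MAP[v]
    raise _err(level, item, row)


@dataclass
class BinaryResponseMatrix:
    """Households x items 0/1 response matrix X_vi.

    ``X`` is float to allow NaN for missing cells (only produced under the
    ``as_missing`` don't-know policy); with the default policy every entry is
    exactly 0.0 or 1.0.
    """

    X: np.ndarray
    household_id: list
    item_id: list
    district: list | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise UserInputError("X must be 2-d (households x items)")
        if len(self.household_id) != self.X.shape[0]:
            raise UserInputError("household_id length does not match X rows")
        if len(self.item_id) != self.X.shape[1]:
            raise UserInputError("item_id length does not match X columns")
        valid = np.isnan(self.X) | (self.X == 0) | (self.X == 1)
        if not valid.all():
            raise UserInputError("X entries must be 0, 1 or missing")
        if self.X.shape[0] and np.isnan(self.X).all(axis=1).any():
            raise UserInputError("all-missing rows must be dropped before construction")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def raw_scores(self) -> np.ndarray:
        """Per-household raw score r_v = sum_i X_vi (NaN-aware)."""
        return np.nansum(self.X, axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.item_id))
        df.insert(0, "household_id", list(self.household_id))
        df.insert(
            1, "district", list(self.district) if self.district is not None else ""
        )
        return df

    def to_csv(self, path) -> None:
        df = self.to_frame()
        # keep 0/1 cells integral in the CSV; missing cells become empty strings
        for c in self.item_id:
            df[c] = df[c].astype("Int64")
        df.to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinaryResponseMatrix":
        item_cols = [c for c in df.columns if c not in ("household_id", "district")]
        district = df["district"].tolist() if "district" in df.columns else None
        hh = (
            df["household_id"].tolist()
            if "household_id" in df.columns
            else list(range(len(df)))
        )
        X = df[item_cols].to_numpy(dtype=float)
        return cls(X=X, household_id=hh, item_id=item_cols, district=district)

    @classmethod
    def from_csv(cls, path) -> "BinaryResponseMatrix":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class CodingLog:
    """Per-item level counts plus warnings accumulated while coding."""

    level_counts: dict = field(default_factory=dict)
    dropped_rows: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def count(self, item, level):
        key = "binary" if isinstance(_normalize(level), int) else str(_normalize(level))
        self.level_counts.setdefault(item, {})
        self.level_counts[item][key] = self.level_counts[item].get(key, 0) + 1

    def to_dict(self) -> dict:
        return {
            "level_counts": self.level_counts,
            "dropped_rows": self.dropped_rows,
            "warnings": self.warnings,
        }


def _coder_for(item: str):
    if item in FREQUENCY_ITEMS:
        return "frequency"
    if item in HOW_OFTEN_ITEMS:
        return "how_often"
    return "yes_no"


def build_binary_matrix(
    raw: pd.DataFrame,
    dk_policy: str = "as_negative",
    level_map: dict | None = None,
    item_ids=DEFAULT_ITEM_IDS,
):
    """Code a raw survey table into a :class:`BinaryResponseMatrix`.

    Parameters
    ----------
    raw : DataFrame with columns ``household_id``, optionally ``district``,
        and one column per item id.  Cells may be raw categorical levels or
        already-binary 0/1 values (coding is idempotent on binary input).
    dk_policy : how to code "don't know" on yes/no items: ``as_negative``
        (0, default) or ``as_missing`` (NaN in the output matrix).
    level_map : optional mapping from bespoke raw spellings to canonical
        levels, applied cell-wise before coding.
    item_ids : item columns to code, in order; any subset of the default 18
        is allowed (k is inferred).

    Returns
    -------
    (BinaryResponseMatrix, CodingLog)

    Notes
    -----
    Follow-up items (E8, E13, E16) are forced to 0 whenever their gate
    question (E7, E12, E15) codes to 0 — a skipped follow-up is not an
    affirmation.  A follow-up present while its gate is missing is honored as
    coded, with a warning.  Rows with every item missing are dropped and
    logged.
    """
    item_ids = [c for c in item_ids]
    missing_cols = [c for c in item_ids if c not in raw.columns]
    if missing_cols:
        raise UserInputError(f"raw table lacks item columns: {missing_cols}")

    log = CodingLog()
    n = len(raw)
    X = np.full((n, len(item_ids)), np.nan)
    hh = (
        raw["household_id"].tolist()
        if "household_id" in raw.columns
        else list(range(n))
    )
    district = raw["district"].tolist() if "district" in raw.columns else None

    for j, item in enumerate(item_ids):
        kind = _coder_for(item)
        col = raw[item].tolist()
        for v_idx, level in enumerate(col):
            if level_map is not None:
                key = level if level in level_map else str(level)
                level = level_map.get(key, level)
            if _normalize(level) is None:
                continue  # missing cell: stays NaN
            log.count(item, level)
            if kind == "frequency":
                X[v_idx, j] = code_frequency_item(level, item=item, row=hh[v_idx])
            elif kind == "how_often":
                X[v_idx, j] = code_how_often(level, item=item, row=hh[v_idx])
            else:
                val = code_yes_no(level, dk_policy, item=item, row=hh[v_idx])
                X[v_idx, j] = np.nan if val is MISSING else val

    # gate logic for the how-often follow-ups
    pos = {item: j for j, item in enumerate(item_ids)}
    for fu, gate in GATE_OF.items():
        if fu not in pos or gate not in pos:
            continue
        g, f = X[:, pos[gate]], X[:, pos[fu]]
        forced = (g == 0) & (f == 1)
        if forced.any():
            log.warnings.append(
                f"{fu}: {int(forced.sum())} affirmative follow-up(s) forced to 0 "
                f"because gate {gate} is negative"
            )
        f[g == 0] = 0.0
        orphan = np.isnan(g) & ~np.isnan(f)
        if orphan.any():
            log.warnings.append(
                f"{fu}: {int(orphan.sum())} follow-up(s) coded while gate {gate} "
                "is missing; follow-up honored as coded"
            )

    keep = ~np.isnan(X).all(axis=1)
    if not keep.all():
        log.dropped_rows = [hh[i] for i in np.flatnonzero(~keep)]
        log.warnings.append(f"dropped {len(log.dropped_rows)} all-missing row(s)")
    X = X[keep]
    hh = [h for h, k_ in zip(hh, keep) if k_]
    if district is not None:
        district = [d for d, k_ in zip(district, keep) if k_]

    matrix = BinaryResponseMatrix(X=X, household_id=hh, item_id=item_ids, district=district)
    return matrix, log


def as_binary_matrix(data) -> BinaryResponseMatrix:
    """Coerce an ndarray / DataFrame / BinaryResponseMatrix to the latter."""
    if isinstance(data, BinaryResponseMatrix):
        return data
    if isinstance(data, pd.DataFrame):
        return BinaryResponseMatrix.from_frame(data)
    X = np.asarray(data, dtype=float)
    return BinaryResponseMatrix(
        X=X,
        household_id=list(range(X.shape[0])),
        item_id=[f"E{i + 1}" for i in range(X.shape[1])],
    )
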