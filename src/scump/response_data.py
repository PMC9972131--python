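"""Likert-type response matrices: loading, validation, and preprocessing.

A response matrix holds integer responses on an ordered categorical scale
(default 1..5), one row per respondent and one column per item, together
with a boolean mask of missing cells.  A labeled sample additionally
carries a binary class label per row (0 = human, 1 = bot).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tokens treated as missing by default when reading delimited text.
DEFAULT_MISSING_CODES = frozenset({"", "NA", "NaN"})


class ResponseDataError(ValueError):
    """Raised for malformed or out-of-contract response data."""


@dataclass(frozen=True)
class ResponseMatrix:
    """Integer Likert responses for ``n`` respondents on ``d`` items.

    Parameters
    ----------
    values
        ``(n, d)`` integer array.  Entries under ``missing_mask`` are
        placeholders and carry no meaning until imputation.
    categories
        Inclusive ``(low, high)`` category bounds; default ``(1, 5)``.
    missing_mask
        ``(n, d)`` boolean array, ``True`` where the response is missing.
    item_ids, row_ids
        Column and row identifiers.  Item ids must be unique.
    """

    values: np.ndarray
    categories: tuple[int, int] = (1, 5)
    missing_mask: np.ndarray | None = None
    item_ids: tuple[str, ...] | None = None
    row_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ResponseDataError("response values must be a 2-D array")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(values == np.floor(values)):
                raise ResponseDataError("responses must be integers")
            values = values.astype(np.int64)
        object.__setattr__(self, "values", values)
        n, d = values.shape
        if n < 1 or d < 2:
            raise ResponseDataError(f"need n >= 1 and d >= 2, got n={n}, d={d}")
        low, high = self.categories
        if not (isinstance(low, (int, np.integer)) and isinstance(high, (int, np.integer))):
            raise ResponseDataError("category bounds must be integers")
        if high <= low:
            raise ResponseDataError("category upper bound must exceed lower bound")
        mask = self.missing_mask
        if mask is None:
            mask = np.zeros_like(values, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != values.shape:
                raise ResponseDataError("missing_mask shape must match values")
        object.__setattr__(self, "missing_mask", mask)
        observed = values[~mask]
        if observed.size and (observed.min() < low or observed.max() > high):
            bad = observed[(observed < low) | (observed > high)]
            raise ResponseDataError(
                f"responses outside category bounds [{low}, {high}]: "
                f"e.g. {bad[:5].tolist()}"
            )
        if self.item_ids is not None:
            ids = tuple(str(i) for i in self.item_ids)
            if len(ids) != d:
                raise ResponseDataError("item_ids length must equal number of items")
            if len(set(ids)) != d:
                raise ResponseDataError("item_ids must be unique")
            object.__setattr__(self, "item_ids", ids)
        if self.row_ids is not None:
            rids = tuple(str(i) for i in self.row_ids)
            if len(rids) != n:
                raise ResponseDataError("row_ids length must equal number of rows")
            object.__setattr__(self, "row_ids", rids)

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def n_categories(self) -> int:
        low, high = self.categories
        return high - low + 1

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def effective_item_ids(self) -> tuple[str, ...]:
        if self.item_ids is not None:
            return self.item_ids
        return tuple(f"item{j + 1}" for j in range(self.n_items))

    def take_rows(self, index: np.ndarray) -> "ResponseMatrix":
        """Row subset/reorder, preserving ids and mask."""
        index = np.asarray(index)
        rids = None
        if self.row_ids is not None:
            rids = tuple(self.row_ids[i] for i in index)
        return replace(
            self,
            values=self.values[index],
            missing_mask=self.missing_mask[index],
            row_ids=rids,
        )


@dataclass(frozen=True)
class LabeledSample:
    """A response matrix plus one binary class label per row.

    Class 0 is human, class 1 is bot.  The calibration design is
    stratified, so at least two rows of each class are required for the
    per-class feature parameters to be estimable.
    """

    responses: ResponseMatrix
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1 or labels.shape[0] != self.responses.n_respondents:
            raise ResponseDataError("labels length must equal number of rows")
        if not np.isin(labels, (0, 1)).all():
            raise ResponseDataError("labels must be binary 0/1")
        labels = labels.astype(np.int64)
        object.__setattr__(self, "labels", labels)
        if self.n_humans < 2:
            raise ResponseDataError(f"need at least 2 human rows, got {self.n_humans}")
        if self.n_bots < 2:
            raise ResponseDataError(f"need at least 2 bot rows, got {self.n_bots}")

    @property
    def n_humans(self) -> int:
        return int(np.sum(self.labels == 0))

    @property
    def n_bots(self) -> int:
        return int(np.sum(self.labels == 1))

    def humans(self) -> ResponseMatrix:
        return self.responses.take_rows(np.flatnonzero(self.labels == 0))

    def bots(self) -> ResponseMatrix:
        return self.responses.take_rows(np.flatnonzero(self.labels == 1))


def read_response_matrix(
    path,
    *,
    delimiter: str = ",",
    missing_codes=DEFAULT_MISSING_CODES,
    categories: tuple[int, int] = (1, 5),
    id_column: str | None = None,
    label_column: str | None = None,
    drop_all_missing_rows: bool = True,
):
    """Read a delimited text file into a :class:`ResponseMatrix`.

    The file must have one header row of item names and one row per
    respondent.  Cells matching ``missing_codes`` set the missing mask.
    Rows whose items are all missing are dropped (with a logged warning)
    before any downstream imputation.

    If ``label_column`` is given, that column is split off as binary
    class labels and a :class:`LabeledSample` is returned instead.
    """
    try:
        frame = pd.read_csv(path, sep=delimiter, header=0, dtype=str,
                            keep_default_na=False, skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ResponseDataError(f"could not parse {path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise ResponseDataError(f"{path}: expected at least two columns")

    row_ids = None
    if id_column is not None:
        if id_column not in frame.columns:
            raise ResponseDataError(f"id column {id_column!r} not found in header")
        row_ids = tuple(frame.pop(id_column).astype(str))

    labels = None
    if label_column is not None:
        if label_column not in frame.columns:
            raise ResponseDataError(f"label column {label_column!r} not found in header")
        raw = frame.pop(label_column).astype(str).str.strip()
        try:
            labels = raw.astype(int).to_numpy()
        except ValueError as exc:
            raise ResponseDataError(f"labels must be integers 0/1: {exc}") from exc

    item_ids = tuple(frame.columns)
    raw = frame.to_numpy(dtype=object)
    missing_codes = {str(c) for c in missing_codes}
    mask = np.zeros(raw.shape, dtype=bool)
    values = np.zeros(raw.shape, dtype=np.int64)
    low, _ = categories
    for (i, j), cell in np.ndenumerate(raw):
        token = str(cell).strip()
        if token in missing_codes:
            mask[i, j] = True
            values[i, j] = low  # placeholder under the mask
            continue
        try:
            values[i, j] = int(token)
        except ValueError:
            raise ResponseDataError(
                f"non-integer cell {token!r} at row {i + 1}, column {item_ids[j]!r}"
            ) from None

    if drop_all_missing_rows:
        all_missing = mask.all(axis=1)
        if all_missing.any():
            logger.warning(
                "dropping %d row(s) with all items missing", int(all_missing.sum())
            )
            keep = ~all_missing
            values, mask = values[keep], mask[keep]
            if row_ids is not None:
                row_ids = tuple(r for r, k in zip(row_ids, keep) if k)
            if labels is not None:
                labels = labels[keep]

    rm = ResponseMatrix(values=values, categories=categories,
                        missing_mask=mask, item_ids=item_ids, row_ids=row_ids)
    if labels is not None:
        return LabeledSample(responses=rm, labels=labels)
    return rm


def write_response_matrix(rm: ResponseMatrix, path, *, delimiter: str = ",",
                          missing_token: str = "NA") -> None:
    """Write a response matrix back to delimited text (round-trip safe)."""
    data = rm.values.astype(object)
    data[rm.missing_mask] = missing_token
    frame = pd.DataFrame(data, columns=rm.effective_item_ids())
    if rm.row_ids is not None:
        frame.insert(0, "row_id", rm.row_ids)
    frame.to_csv(path, sep=delimiter, index=False)


def impute_middle(rm: ResponseMatrix) -> ResponseMatrix:
    """Replace every missing cell with the middle category.

    Requires an odd number of categories so the middle is unambiguous;
    for the default 1..5 scale the middle category is 3.  Idempotent.
    """
    if rm.n_categories % 2 == 0:
        raise ResponseDataError(
            f"cannot impute the middle of an even number of categories "
            f"({rm.n_categories}): no unique middle exists"
        )
    if not rm.has_missing:
        return rm
    low, high = rm.categories
    middle = (low + high) // 2
    values = rm.values.copy()
    values[rm.missing_mask] = middle
    return replace(rm, values=values, missing_mask=np.zeros_like(rm.missing_mask))
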