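"""The feature-table container passed between all pipeline stages.

A :class:`FeatureTable` is a samples x features matrix with a per-feature
*kind* tag distinguishing continuous molecular descriptors from binary
fingerprint bits.  It is a thin, validated wrapper around a pandas
DataFrame; the DataFrame index holds sample identifiers and the columns
hold unique feature names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

DESCRIPTOR = "descriptor"
FINGERPRINT_BIT = "fingerprint_bit"
_KINDS = frozenset({DESCRIPTOR, FINGERPRINT_BIT})


@dataclass
class FeatureTable:
    """Samples x named features with a per-feature kind tag.

    Parameters
    ----------
    values
        DataFrame of shape (n_samples, n_features); index = sample ids,
        columns = feature names (unique).
    kinds
        Mapping feature name -> ``"descriptor"`` or ``"fingerprint_bit"``,
        covering every column.  Fingerprint columns must contain only 0/1.
    """

    values: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        cols = list(self.values.columns)
        if len(cols) != len(set(cols)):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise SchemaError(f"duplicate feature names: {dupes}")
        missing = [c for c in cols if c not in self.kinds]
        if missing:
            raise SchemaError(f"features without a kind tag: {missing[:5]}")
        bad = {k: v for k, v in self.kinds.items() if v not in _KINDS}
        if bad:
            raise SchemaError(f"unknown feature kinds: {bad}")
        self.kinds = {c: self.kinds[c] for c in cols}  # drop stale entries, fix order
        fp_cols = [c for c in cols if self.kinds[c] == FINGERPRINT_BIT]
        if fp_cols:
            fp = self.values[fp_cols].to_numpy()
            if not np.isin(fp, (0, 1)).all():
                raise SchemaError("fingerprint columns must contain only 0/1 values")

    # -- basic views ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def kind_of(self, name: str) -> str:
        return self.kinds[name]

    # -- subsetting -----------------------------------------------------
    def select(self, names: Sequence[str]) -> "FeatureTable":
        """Return a new table restricted to ``names`` (in the given order)."""
        return FeatureTable(self.values[list(names)].copy(),
                            {n: self.kinds[n] for n in names})

    def drop(self, names: Iterable[str]) -> "FeatureTable":
        names = set(names)
        keep = [c for c in self.feature_names if c not in names]
        return self.select(keep)

    def take_rows(self, ids: Sequence) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(ids)].copy(), dict(self.kinds))

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.kinds == other.kinds and self.values.equals(other.values)

    # -- I/O: CSV matrix + JSON sidecar with the kind tags ---------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.values.to_csv(path, index_label="id")
        sidecar = path.with_suffix(path.suffix + ".kinds.json")
        sidecar.write_text(json.dumps(self.kinds, indent=0, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path,
                 kinds: Mapping[str, str] | None = None) -> "FeatureTable":
        path = Path(path)
        values = pd.read_csv(path, index_col="id")
        if kinds is None:
            sidecar = path.with_suffix(path.suffix + ".kinds.json")
            if sidecar.exists():
                kinds = json.loads(sidecar.read_text())
            else:
                # fall back to the package naming convention
                kinds = {c: (FINGERPRINT_BIT if c.startswith("fp_") else DESCRIPTOR)
                         for c in values.columns}
        return cls(values, dict(kinds))


def uniform_kinds(names: Iterable[str], kind: str) -> dict[str, str]:
    """Convenience: tag every feature in ``names`` with the same kind."""
    if kind not in _KINDS:
        raise SchemaError(f"unknown feature kind: {kind!r}")
    return {n: kind for n in names}
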