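"""Self-archiving feature repository with case-vs-group decision support.

The repository is a JSON-lines file: one :class:`FeatureRecord` per line,
append-only, with a ``schema_version`` field per record.  It stores ROI
histogram features only, never images, and holds the group statistics the
threshold classifier trains on.  The case-vs-group comparison report places
an index case against each stored tumour group: per feature, the group
mean, standard deviation, the index value, its z-score, and whether it lies
within one standard deviation of the group mean.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from miror.imaging_io import MAP_KINDS
from miror.roi_features import FeatureVector

SCHEMA_VERSION = 1

GROUPS = ("malignant", "benign", "unknown")


@dataclass
class FeatureRecord:
    """One case's ROI features on one map kind — a repository row."""

    case_id: str
    group: str
    map_kind: str
    features: dict[str, float]
    diagnosis: str = ""
    nbins: int = 256
    created: str = ""
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.map_kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.map_kind!r}")
        if not self.features:
            raise ValueError("features must be non-empty")
        if isinstance(self.features, FeatureVector):
            self.features = self.features.as_dict()
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat(timespec="seconds")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "FeatureRecord":
        return cls(**json.loads(line))


@dataclass
class GroupStats:
    """Per-feature mean/SD of one tumour group on one map kind.

    This is the trained model of the threshold classifier: a case is
    compared against ``mean ± sd`` membership intervals per feature.
    """

    group: str
    map_kind: str
    means: dict[str, float]
    sds: dict[str, float]
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group statistics need >= 2 records")
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("SD must be non-negative")


class Repository:
    """In-memory view of a JSON-lines feature repository."""

    def __init__(self, records: list[FeatureRecord] | None = None):
        self.records: list[FeatureRecord] = []
        for r in records or []:
            self.add(r)

    def __len__(self) -> int:
        return len(self.records)

    # -- persistence --------------------------------------------------------

    @classmethod
    def load(cls, path) -> "Repository":
        path = Path(path)
        repo = cls()
        if path.exists():
            for line in path.read_text().splitlines():
                if line.strip():
                    repo.add(FeatureRecord.from_json(line))
        return repo

    def save(self, path) -> None:
        Path(path).write_text("".join(r.to_json() + "\n" for r in self.records))

    # -- core operations ----------------------------------------------------

    def add(self, record: FeatureRecord, overwrite: bool = False) -> "Repository":
        """Append a record; a duplicate (case_id, map_kind) is an error
        unless ``overwrite`` is set."""
        existing = [i for i, r in enumerate(self.records)
                    if r.case_id == record.case_id and r.map_kind == record.map_kind]
        if existing:
            if not overwrite:
                raise ValueError(
                    f"duplicate record for case {record.case_id!r} / {record.map_kind}"
                )
            for i in reversed(existing):
                del self.records[i]
        self.records.append(record)
        return self

    def query(self, group: str | None = None, map_kind: str | None = None
              ) -> list[FeatureRecord]:
        """Records matching all given filters, in insertion order."""
        out = self.records
        if group is not None:
            out = [r for r in out if r.group == group]
        if map_kind is not None:
            out = [r for r in out if r.map_kind == map_kind]
        return list(out)

    def group_summary(self, group: str, map_kind: str | None = None,
                      sample_sd: bool = False) -> GroupStats:
        """Per-feature mean and (population, by default) SD of a group."""
        recs = self.query(group=group, map_kind=map_kind)
        if len(recs) < 2:
            raise ValueError(
                f"need >=2 records for group {group!r}/{map_kind}, have {len(recs)}"
            )
        keys = set(recs[0].features)
        for r in recs[1:]:
            keys &= set(r.features)
        keys -= {"n_voxels", "volume_ml", "degenerate"}
        ddof = 1 if sample_sd else 0
        means, sds = {}, {}
        for k in sorted(keys):
            vals = np.array([float(r.features[k]) for r in recs])
            means[k] = float(vals.mean())
            sds[k] = float(vals.std(ddof=ddof))
        return GroupStats(group=group, map_kind=map_kind or "any",
                          means=means, sds=sds, n=len(recs))

    def compare_case(self, index_features, map_kind: str | None = None,
                     groups: tuple[str, ...] = ("malignant", "benign")
                     ) -> list[dict]:
        """Case-vs-group comparison report for decision support.

        Returns one row per (feature, group): group mean, SD, the index
        case's value, its z-score (None when SD is zero) and an
        inside-one-SD flag.
        """
        if isinstance(index_features, FeatureVector):
            index_features = index_features.as_dict()
        rows = []
        for group in groups:
            gs = self.group_summary(group, map_kind=map_kind)
            for feat, mean in gs.means.items():
                if feat not in index_features:
                    continue
                value = float(index_features[feat])
                sd = gs.sds[feat]
                z = (value - mean) / sd if sd > 0 else None
                inside = abs(value - mean) <= sd
                rows.append({
                    "feature": feat,
                    "group": group,
                    "group_mean": mean,
                    "group_sd": sd,
                    "group_n": gs.n,
                    "index_value": value,
                    "z_score": z,
                    "inside_1sd": inside,
                })
        return rows
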