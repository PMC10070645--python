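"""Feature blocks: one data type's subject-by-variable table with kind tags.

A cohort is integrated from several *blocks* (data types). Each block is a
table over the same ordered subjects, and each variable carries a kind tag:

- ``numeric``: a real-valued measurement,
- ``ordinal3``: an ordered 3-level category coded 0/1/2,
- ``zero_inflated_count``: a nonnegative count with a point mass at zero,
  which preprocessing recodes to ``ordinal3``.

A block's role decides its downstream treatment: ``mixed`` blocks (numeric +
ordinal) are range-standardized and compared with Gower distance;
``numeric_only`` blocks are z-scored and compared with Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

VALID_KINDS = ("numeric", "ordinal3", "zero_inflated_count")
VALID_ROLES = ("mixed", "numeric_only")


@dataclass
class FeatureBlock:
    """One data type's subject x variable table.

    Parameters
    ----------
    name : str
        Block identifier (e.g. ``"block1"``).
    values : pandas.DataFrame
        Subjects in rows (index = subject ids), variables in columns.
    kinds : dict of str to str
        Per-variable kind, one of ``numeric``, ``ordinal3``,
        ``zero_inflated_count``; keys must match the columns exactly.
    block_role : str
        ``"mixed"`` or ``"numeric_only"``.
    """

    name: str
    values: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)
    block_role: str = "numeric_only"

    def __post_init__(self) -> None:
        if self.block_role not in VALID_ROLES:
            raise ValueError(
                f"block_role must be one of {VALID_ROLES}, got {self.block_role!r}"
            )
        if list(self.kinds) != list(self.values.columns):
            raise ValueError(
                f"block {self.name!r}: kinds keys {list(self.kinds)} do not match "
                f"columns {list(self.values.columns)}"
            )
        for var, kind in self.kinds.items():
            if kind not in VALID_KINDS:
                raise ValueError(f"variable {var!r}: unknown kind {kind!r}")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(
                f"block {self.name!r} has missing entries in {bad}; subjects with "
                "missing in-model data must be removed before constructing a block"
            )
        if self.block_role == "numeric_only" and any(
            k != "numeric" for k in self.kinds.values()
        ):
            raise ValueError(
                f"block {self.name!r} is numeric_only but has non-numeric kinds"
            )
        ord_cols = [v for v, k in self.kinds.items() if k == "ordinal3"]
        for var in ord_cols:
            vals = np.asarray(self.values[var])
            if not np.isin(vals, (0, 1, 2)).all():
                raise ValueError(f"ordinal3 variable {var!r} has values outside {{0,1,2}}")

    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def numeric_variables(self) -> list[str]:
        return [v for v, k in self.kinds.items() if k == "numeric"]

    def subset(self, subject_ids) -> "FeatureBlock":
        """Return the block restricted to ``subject_ids`` in the given order."""
        return replace(self, values=self.values.loc[list(subject_ids)])

    def copy(self) -> "FeatureBlock":
        return replace(self, values=self.values.copy(), kinds=dict(self.kinds))


def check_aligned(blocks: list[FeatureBlock]) -> list:
    """Validate that all blocks share one subject index in identical order."""
    if not blocks:
        raise ValueError("no blocks given")
    ids = blocks[0].subject_ids
    for b in blocks[1:]:
        if b.subject_ids != ids:
            raise ValueError(
                f"blocks {blocks[0].name!r} and {b.name!r} do not share the same "
                "subject index/order"
            )
    return ids


# ---------------------------------------------------------------------------
# manifest + block IO


def write_manifest(blocks: list[FeatureBlock], path) -> None:
    manifest = {
        "blocks": {
            b.name: {"role": b.block_role, "variables": dict(b.kinds)} for b in blocks
        }
    }
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_blocks(directory, manifest_path=None) -> list[FeatureBlock]:
    """Load ``<name>.csv`` per block listed in ``manifest.yaml``."""
    directory = Path(directory)
    manifest_path = Path(manifest_path or directory / "manifest.yaml")
    manifest = yaml.safe_load(manifest_path.read_text())
    blocks = []
    for name, entry in manifest["blocks"].items():
        df = pd.read_csv(directory / f"{name}.csv", index_col=0)
        if df.isna().any().any():
            raise ValueError(
                f"block {name!r}: missing in-model data; such subjects are rejected "
                "at load time"
            )
        blocks.append(
            FeatureBlock(
                name=name,
                values=df,
                kinds=dict(entry["variables"]),
                block_role=entry["role"],
            )
        )
    check_aligned(blocks)
    return blocks


def write_blocks(blocks: list[FeatureBlock], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for b in blocks:
        b.values.to_csv(directory / f"{b.name}.csv")
    write_manifest(blocks, directory / "manifest.yaml")
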