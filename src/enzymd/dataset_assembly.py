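"""Feature-table assembly: replicate aggregation, block concatenation,
min-max rescaling, the 80/20 split and the seven feature-block subsets.

The assembled table has 192 columns under the default featurization: 80
sequence/structure (SEQ), 32 molecular-dynamics (MD) and 80 pocket
(POCKET) descriptors, in that order, with the FCA response attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "BLOCKS",
    "aggregate_replicates",
    "assemble_feature_table",
    "minmax_scale",
    "inverse_minmax",
    "train_test_split",
    "block_subsets",
    "BLOCK_COMBINATIONS",
]

BLOCKS = ("SEQ", "MD", "POCKET")

#: the seven benchmark feature-set combinations
BLOCK_COMBINATIONS = {
    "Seq+MD+MDpocket": ("SEQ", "MD", "POCKET"),
    "Seq+MD": ("SEQ", "MD"),
    "MD+MDpocket": ("MD", "POCKET"),
    "Seq+MDpocket": ("SEQ", "POCKET"),
    "Seq": ("SEQ",),
    "MD": ("MD",),
    "MDpocket": ("POCKET",),
}


def _aggregation_tag(name: str) -> str:
    if name.endswith("_mean"):
        return "mean"
    if name.endswith("_std"):
        return "std"
    return "na"


@dataclass
class FeatureTable:
    """Variants x features with per-feature block tags and an optional
    response vector."""

    values: pd.DataFrame  # index: variant ids; columns: feature names
    blocks: dict[str, str]  # feature name -> SEQ | MD | POCKET
    response: np.ndarray | None = None  # FCA, aligned with the index

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = sorted(set(self.values.columns[self.values.columns.duplicated()]))
            raise ValueError(f"duplicate feature names: {dupes}")
        missing = [c for c in self.values.columns if c not in self.blocks]
        if missing:
            raise ValueError(f"features without block tag: {missing}")
        if self.values.isna().any().any():
            raise ValueError("assembled feature table contains missing values")
        if self.response is not None:
            self.response = np.asarray(self.response, dtype=float)
            if len(self.response) != len(self.values):
                raise ValueError("response length does not match variant count")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def aggregation(self, name: str) -> str:
        return _aggregation_tag(name)

    def block_width(self, block: str) -> int:
        return sum(1 for b in self.blocks.values() if b == block)

    def with_response(self, response) -> "FeatureTable":
        return FeatureTable(self.values.copy(), dict(self.blocks),
                            np.asarray(response, dtype=float))

    def subset_rows(self, rows) -> "FeatureTable":
        resp = self.response[rows] if self.response is not None else None
        return FeatureTable(self.values.iloc[rows].copy(), dict(self.blocks), resp)

    def subset_blocks(self, keep: tuple[str, ...]) -> "FeatureTable":
        cols = [c for c in self.values.columns if self.blocks[c] in keep]
        blocks = {c: self.blocks[c] for c in cols}
        return FeatureTable(self.values[cols].copy(), blocks, self.response)

    # ---- tagged-CSV representation (io_formats round-trip) ----

    def to_frame(self, tagged: bool = False) -> pd.DataFrame:
        if not tagged:
            return self.values.copy()
        df = self.values.copy()
        df.columns = [f"{self.blocks[c]}:{c}" for c in df.columns]
        if self.response is not None:
            df["FCA"] = self.response
        return df

    @classmethod
    def from_tagged_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        response = None
        if "FCA" in df.columns:
            response = df["FCA"].to_numpy(dtype=float)
            df = df.drop(columns=["FCA"])
        names, blocks = [], {}
        for col in df.columns:
            if ":" not in col:
                raise ValueError(f"column {col!r} lacks a BLOCK: tag")
            block, name = col.split(":", 1)
            if block not in BLOCKS:
                raise ValueError(f"unknown block tag {block!r} in column {col!r}")
            names.append(name)
            blocks[name] = block
        out = df.copy()
        out.columns = names
        return cls(out, blocks, response)


def aggregate_replicates(
    per_replicate: list[dict[str, float]],
) -> tuple[dict[str, float], dict[str, float]]:
    """Mean and population std (ddof=0) over replicate feature vectors."""
    if not per_replicate:
        raise ValueError("need at least one replicate")
    keys = list(per_replicate[0])
    for rep in per_replicate[1:]:
        if list(rep) != keys:
            raise ValueError("replicates disagree on feature names")
    arr = np.array([[rep[k] for k in keys] for rep in per_replicate], dtype=float)
    mean = dict(zip(keys, arr.mean(axis=0)))
    std = dict(zip(keys, arr.std(axis=0, ddof=0)))
    return mean, std


def assemble_feature_table(
    seq_block: pd.DataFrame | None,
    md_block: pd.DataFrame | None,
    pocket_block: pd.DataFrame | None,
    response=None,
) -> FeatureTable:
    """Concatenate the feature blocks in SEQ, MD, POCKET order.

    All present blocks must agree on variant ids; duplicate feature names
    across blocks are rejected.
    """
    present = [(name, blk) for name, blk in
               (("SEQ", seq_block), ("MD", md_block), ("POCKET", pocket_block))
               if blk is not None]
    if not present:
        raise ValueError("at least one feature block is required")
    ids = list(present[0][1].index)
    for name, blk in present[1:]:
        if list(blk.index) != ids:
            offenders = sorted(set(blk.index).symmetric_difference(ids))
            raise ValueError(f"variant id mismatch in block {name}: {offenders}")
    blocks: dict[str, str] = {}
    for name, blk in present:
        for col in blk.columns:
            if col in blocks:
                raise ValueError(f"duplicate feature name across blocks: {col!r}")
            blocks[col] = name
    values = pd.concat([blk for _, blk in present], axis=1)
    return FeatureTable(values, blocks, response)


def minmax_scale(
    table: FeatureTable, fit_rows: np.ndarray | None = None
) -> tuple[FeatureTable, pd.DataFrame]:
    """Min-max rescale every feature using extrema from ``fit_rows`` only
    (all rows when None).  Constant columns map to 0; values outside the
    fitted range scale beyond [0, 1] without clipping."""
    df = table.values
    fit = df if fit_rows is None else df.iloc[fit_rows]
    if len(fit) == 0:
        raise ValueError("fit_rows must be non-empty")
    lo, hi = fit.min(axis=0), fit.max(axis=0)
    span = (hi - lo).replace(0.0, np.nan)
    scaled = ((df - lo) / span).fillna(0.0)
    params = pd.DataFrame({"min": lo, "max": hi})
    return FeatureTable(scaled, dict(table.blocks), table.response), params


def inverse_minmax(scaled: FeatureTable, params: pd.DataFrame) -> pd.DataFrame:
    span = params["max"] - params["min"]
    return scaled.values * span + params["min"]


def train_test_split(
    table: FeatureTable, train_frac: float = 0.8, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Random unstratified split; train size = floor(train_frac * n), so a
    312-variant table yields 249 training and 63 test rows."""
    n = len(table.values)
    if n < 5:
        raise ValueError("too few rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(train_frac * n))
    return table.subset_rows(perm[:n_train]), table.subset_rows(perm[n_train:])


def block_subsets(table: FeatureTable) -> dict[str, FeatureTable]:
    """The seven benchmark combinations of the SEQ, MD and POCKET blocks."""
    for block in BLOCKS:
        if table.block_width(block) == 0:
            raise ValueError(f"feature table lacks block {block}")
    return {name: table.subset_blocks(keep)
            for name, keep in BLOCK_COMBINATIONS.items()}
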