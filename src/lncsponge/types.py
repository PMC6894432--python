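"""Core domain containers shared by every pipeline stage.

All containers wrap validated :class:`pandas.DataFrame` objects so they can be
sliced, joined and written with the usual pandas idioms, while construction
enforces the invariants the pipeline relies on (unique identifiers, finite
values, consistent tumor/normal pairing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("mRNA", "lncRNA", "miRNA")
UNITS = ("counts", "CPM", "FPKM", "log2CPM", "log2FPKM")
LOG_UNITS = ("log2CPM", "log2FPKM")
CONDITIONS = ("tumor", "normal")
TNM_STAGES = ("I", "II", "III", "IV")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with a molecule role and a unit tag.

    Parameters
    ----------
    data
        Numeric DataFrame, index = gene ids, columns = sample ids.
    role
        One of ``mRNA``, ``lncRNA``, ``miRNA``.
    unit
        One of ``counts``, ``CPM``, ``FPKM``, ``log2CPM``, ``log2FPKM``.
        Non-log units must be non-negative.
    """

    data: pd.DataFrame
    role: str
    unit: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        if self.unit not in LOG_UNITS and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r} "
                f"(unit {self.unit!r} must be non-negative)"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.role, self.unit)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.role, self.unit)


CLINICAL_COLUMNS = (
    "sample_id",
    "patient_id",
    "condition",
    "pair_id",
    "tnm_stage",
    "survival_time",
    "event",
)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations: condition, pairing, stage, survival.

    ``pair_id`` links exactly one tumor and one normal sample; ``tnm_stage``
    is recorded on tumor samples; ``survival_time`` (days) and ``event``
    (1 = death, 0 = censored) are per patient and must appear together.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"clinical table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown condition values: {sorted(bad_cond)}")
        staged = df["tnm_stage"].dropna()
        bad_stage = set(staged) - set(TNM_STAGES)
        if bad_stage:
            raise ValidationError(f"unknown TNM stages: {sorted(bad_stage)}")
        # survival_time and event must be present together
        has_time = df["survival_time"].notna()
        has_event = df["event"].notna()
        if (has_time != has_event).any():
            bad = df.loc[has_time != has_event, "sample_id"].tolist()
            raise ValidationError(
                f"survival_time and event must be present together; offending samples: {bad}"
            )
        times = df.loc[has_time, "survival_time"]
        if (times < 0).any():
            raise ValidationError("negative survival_time")
        events = set(df.loc[has_event, "event"])
        if not events <= {0, 1, 0.0, 1.0}:
            raise ValidationError(f"event values must be 0/1, got {sorted(events)}")
        # every pair_id on exactly one tumor and one normal sample
        paired = df[df["pair_id"].notna()]
        for pair_id, grp in paired.groupby("pair_id"):
            conds = sorted(grp["condition"])
            if conds != ["normal", "tumor"]:
                raise ValidationError(
                    f"pair {pair_id!r} must contain exactly one tumor and one normal "
                    f"sample, got conditions {conds}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def tumor_samples(self) -> list[str]:
        df = self.data
        return list(df.loc[df["condition"] == "tumor", "sample_id"])

    def normal_samples(self) -> list[str]:
        df = self.data
        return list(df.loc[df["condition"] == "normal", "sample_id"])

    def pairs(self) -> pd.DataFrame:
        """Return one row per complete pair: (pair_id, tumor_sample, normal_sample)."""
        df = self.data[self.data["pair_id"].notna()]
        tum = df[df["condition"] == "tumor"].set_index("pair_id")["sample_id"]
        nor = df[df["condition"] == "normal"].set_index("pair_id")["sample_id"]
        out = pd.DataFrame({"tumor_sample": tum, "normal_sample": nor}).dropna()
        out.index.name = "pair_id"
        return out.sort_index().reset_index()


@dataclass
class TargetEdgeTable:
    """Directed miRNA -> target edges from sequence-based binding prediction."""

    data: pd.DataFrame  # columns: mirna_id, target_id; unique rows
    n_duplicates_dropped: int = 0
    _target_map: dict = field(default=None, repr=False, compare=False)
    _mirna_map: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.data
        if list(df.columns) != ["mirna_id", "target_id"]:
            raise ValidationError(
                f"target edge table needs columns ['mirna_id', 'target_id'], got {list(df.columns)}"
            )
        if (df["mirna_id"].astype(str).str.len() == 0).any() or (
            df["target_id"].astype(str).str.len() == 0
        ).any():
            raise ValidationError("empty id in target edge table")
        if df.duplicated().any():
            raise ValidationError("target edge table contains duplicate rows after construction")
        self._target_map = None
        self._mirna_map = None

    @classmethod
    def from_edges(cls, df: pd.DataFrame) -> "TargetEdgeTable":
        """Build from a possibly-duplicated two-column edge frame."""
        df = df.copy()
        df.columns = ["mirna_id", "target_id"]
        n0 = len(df)
        df = df.drop_duplicates().reset_index(drop=True)
        return cls(df, n_duplicates_dropped=n0 - len(df))

    def targets_of(self, mirna_id: str) -> set:
        if self._mirna_map is None:
            self._mirna_map = {
                m: set(g["target_id"]) for m, g in self.data.groupby("mirna_id")
            }
        return self._mirna_map.get(mirna_id, set())

    def mirnas_of(self, target_id: str) -> set:
        if self._target_map is None:
            self._target_map = {
                t: set(g["mirna_id"]) for t, g in self.data.groupby("target_id")
            }
        return self._target_map.get(target_id, set())

    def target_to_mirnas(self) -> dict:
        self.mirnas_of("")  # populate cache
        return dict(self._target_map)

    def mirna_to_targets(self) -> dict:
        self.targets_of("")
        return dict(self._mirna_map)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict  # name -> set of gene ids
    descriptions: dict  # name -> str

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
        unknown = set(self.descriptions) - set(self.sets)
        if unknown:
            raise ValidationError(f"descriptions for unknown sets: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)
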