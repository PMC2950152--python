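"""Core in-memory containers for the comparative-CT pipeline.

Conventions
-----------
* CT matrices are pandas DataFrames with miRNA ids on the rows and sample ids
  on the columns.  "No amplification" wells carry NaN — never 40 or infinity —
  so that detection logic stays explicit.
* Genomic coordinates are 1-based inclusive internally (miRBase/GFF
  convention); BED-style inputs are shifted on load.
* A *condition* is a disease × state label such as ``"UC_quiescent"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

GROUPS = ("control", "UC", "CD")
STATES = ("quiescent", "inflamed", "right_colon", "left_colon")
DISEASES = ("UC", "CD")
DISEASE_STATES = ("quiescent", "inflamed")

#: The four disease × state conditions the dispersion statistics pool over.
DISEASE_CONDITIONS = tuple(
    f"{g}_{s}" for g in DISEASES for s in DISEASE_STATES
)

#: Exact conversion between the ΔΔCT (cycle) scale and the 10×log10 fold scale:
#: one PCR cycle corresponds to 10·log10(2) ≈ 3.0103 units.
LOG_FOLD_PER_CYCLE = 10.0 * np.log10(2.0)


def condition_label(group: str, state: str) -> str:
    return f"{group}_{state}"


def split_condition(condition: str) -> tuple[str, str]:
    group, state = condition.split("_", 1)
    return group, state


def _check_unique(values: Iterable[str], what: str) -> None:
    values = list(values)
    if len(set(values)) != len(values):
        seen: set[str] = set()
        dups = sorted({v for v in values if v in seen or seen.add(v)})
        raise FormatError(f"duplicate {what}: {dups}")


@dataclass
class CtMatrix:
    """Raw threshold-cycle values, miRNAs × samples.

    ``values`` holds one finite positive CT per well, or NaN for wells where
    the target never amplified.  The reference small RNA (default U6) must be
    present as a row; it is excluded from :attr:`mirna_ids`.
    """

    values: pd.DataFrame
    reference_id: str = "U6"

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "miRNA ids")
        _check_unique(self.values.columns, "sample ids")
        if self.reference_id not in self.values.index:
            raise FormatError(
                f"reference RNA {self.reference_id!r} missing from CT matrix"
            )
        vals = self.values.to_numpy(dtype=float)
        bad = np.isfinite(vals) & (vals <= 0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                "CT values must be positive; offending cell "
                f"({self.values.index[r]}, {self.values.columns[c]})"
            )
        if np.isinf(vals).any():
            raise FormatError("CT values must be finite or NaN")
        self.values = self.values.astype(float)

    @property
    def mirna_ids(self) -> list[str]:
        return [m for m in self.values.index if m != self.reference_id]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def without_reference(self) -> pd.DataFrame:
        return self.values.drop(index=self.reference_id)


@dataclass
class SampleTable:
    """Per-sample metadata: subject, disease group, mucosal state, histological grade.

    Grades follow the 0–4 scale: 0–1 quiescent (also seen in controls),
    2–4 inflamed.  A grade ≥2 on a quiescent biopsy (or 0–1 on an inflamed
    one) is rejected, mirroring the exclusion of endoscopically quiescent but
    histologically active samples.
    """

    frame: pd.DataFrame  # index sample_id; columns subject_id, group, state, grade

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "state"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"sample table missing columns: {sorted(missing)}")
        _check_unique(self.frame.index, "sample ids")
        if "grade" not in self.frame.columns:
            self.frame = self.frame.assign(grade=np.nan)
        self.frame = self.frame.copy()
        self.frame["grade"] = pd.to_numeric(self.frame["grade"], errors="coerce")
        bad_group = sorted(set(self.frame["group"]) - set(GROUPS))
        if bad_group:
            raise FormatError(f"unknown group token(s): {bad_group}")
        bad_state = sorted(set(self.frame["state"]) - set(STATES))
        if bad_state:
            raise FormatError(f"unknown state token(s): {bad_state}")
        for sid, row in self.frame.iterrows():
            g = row["grade"]
            if pd.isna(g):
                continue
            if g not in (0, 1, 2, 3, 4):
                raise FormatError(f"sample {sid}: grade {g} outside 0-4")
            inflamed = row["state"] == "inflamed"
            if g >= 2 and not inflamed:
                raise ConsistencyError(
                    f"sample {sid}: histological grade {int(g)} on a "
                    f"{row['state']} biopsy (grades 2-4 imply inflamed mucosa)"
                )
            if g <= 1 and inflamed:
                raise ConsistencyError(
                    f"sample {sid}: grade {int(g)} on an inflamed biopsy "
                    "(grades 0-1 imply quiescent mucosa)"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.frame.index[self.frame["group"] == group])

    def samples_in_condition(self, condition: str) -> list[str]:
        group, state = split_condition(condition)
        mask = (self.frame["group"] == group) & (self.frame["state"] == state)
        return list(self.frame.index[mask])

    def conditions_present(self) -> list[str]:
        out = []
        for cond in DISEASE_CONDITIONS:
            if self.samples_in_condition(cond):
                out.append(cond)
        return out

    def validate_against(self, ct: CtMatrix) -> None:
        missing = set(ct.sample_ids) - set(self.frame.index)
        if missing:
            raise ConsistencyError(
                f"samples in CT matrix absent from metadata: {sorted(missing)}"
            )


@dataclass
class RelExprMatrix:
    """Relative expression per (miRNA, sample): ΔCT, ΔΔCT, fold, 10×log10 fold.

    All four frames share index (miRNAs, reference excluded) and columns
    (samples).  Undetected wells are NaN throughout; fold is strictly positive
    wherever defined and ``log_fold == 10·log10(fold)``.
    """

    delta_ct: pd.DataFrame
    delta_delta_ct: pd.DataFrame
    fold: pd.DataFrame
    log_fold: pd.DataFrame
    control_sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        shape = self.delta_ct.shape
        for name in ("delta_delta_ct", "fold", "log_fold"):
            if getattr(self, name).shape != shape:
                raise FormatError(f"{name} shape differs from delta_ct")
        f = self.fold.to_numpy(dtype=float)
        if np.any(np.isfinite(f) & (f <= 0)):
            raise FormatError("fold values must be positive where defined")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.log_fold.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.log_fold.columns)


@dataclass
class DysregulationCall:
    """The per-(miRNA, condition) verdict of the dual magnitude + significance rule."""

    mirna_id: str
    condition: str
    mean_log_fold: float
    sd_log_fold: float
    direction: str  # up | down | unchanged
    p_value: float
    passes_cutoff: bool
    significant: bool
    n: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "unchanged"):
            raise FormatError(f"bad direction {self.direction!r}")
        if self.significant and not self.passes_cutoff:
            raise FormatError("significant calls must pass the magnitude cut-off")


@dataclass
class MirGeneAnnotation:
    """Genomic location and cytogenetic band of one miRNA gene copy.

    Paralogous copies (e.g. 29b-1 / 29b-2) are distinct records.  Coordinates
    are 1-based inclusive; strand is stored but band grouping ignores it.
    """

    gene_id: str
    mirna_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    band: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise FormatError(f"{self.gene_id}: 1-based start must be >= 1")
        if not self.band:
            raise FormatError(f"{self.gene_id}: empty cytogenetic band")


@dataclass
class LocusSet:
    """Named susceptibility-locus intervals (1-based inclusive internally)."""

    frame: pd.DataFrame  # index locus_id; columns chromosome, start, end, source

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "locus ids")
        required = {"chromosome", "start", "end"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"locus set missing columns: {sorted(missing)}")
        if "source" not in self.frame.columns:
            self.frame = self.frame.assign(source="linkage")
        bad = self.frame["start"] > self.frame["end"]
        if bad.any():
            raise FormatError(
                f"invalid locus interval(s): {list(self.frame.index[bad])}"
            )

    @property
    def locus_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TargetCatalog:
    """miRNA → target-gene interaction records (PITA-style flat catalog).

    Duplicate (miRNA, gene) pairs collapse to the best (lowest, i.e. most
    favourable ΔΔG-like) score on construction.
    """

    pairs: pd.DataFrame  # columns mirna_id, gene_id, score

    def __post_init__(self) -> None:
        required = {"mirna_id", "gene_id"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise FormatError(f"target catalog missing columns: {sorted(missing)}")
        df = self.pairs.copy()
        if "score" not in df.columns:
            df["score"] = np.nan
        df = df.sort_values("score", na_position="last")
        df = df.drop_duplicates(subset=["mirna_id", "gene_id"], keep="first")
        self.pairs = df.reset_index(drop=True)

    @property
    def mirna_ids(self) -> set[str]:
        return set(self.pairs["mirna_id"])

    @property
    def gene_ids(self) -> set[str]:
        return set(self.pairs["gene_id"])

    def genes_for(self, mirnas: Iterable[str]) -> set[str]:
        mirnas = set(mirnas)
        mask = self.pairs["mirna_id"].isin(mirnas)
        return set(self.pairs.loc[mask, "gene_id"])

    def mirnas_for(self, gene: str) -> set[str]:
        mask = self.pairs["gene_id"] == gene
        return set(self.pairs.loc[mask, "mirna_id"])

    def __len__(self) -> int:
        return len(self.pairs)
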