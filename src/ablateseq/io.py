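"""Data model and on-disk formats for ablation time-course experiments.

Everything on disk is tab-separated UTF-8 text without quoting; lines
beginning with ``#`` are comments.  Three tables describe an experiment:

counts
    ``transcript_id`` and ``length_nt`` columns followed by one integer
    column per sample.
library sizes
    a header line of sample ids and a single data line of total mapped
    reads per sample.  Optional: when absent, column sums are used with a
    warning (column sums undercount reads mapped outside the retained
    transcript set, which is why an explicit table is preferred).
design
    columns ``sample_id, arm, condition, day, replicate`` describing the
    two treatment arms (``irradiation`` and ``rnai``), each with one
    control condition and a strictly increasing series of treated days.

Annotations (for enrichment analysis) arrive as a two-column TSV of
``transcript_id, term_id`` pairs.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from ._utils import sha256_file

logger = logging.getLogger(__name__)

ARMS = ("irradiation", "rnai")
CONDITIONS = ("treated", "control")

__all__ = [
    "ARMS",
    "CONDITIONS",
    "StudyDesign",
    "CountMatrix",
    "AnnotationTable",
    "load_design",
    "load_dataset",
    "load_annotations",
    "write_results",
    "write_dataset",
    "sha256_file",
]


class StudyDesign:
    """Validated sample sheet for a two-arm ablation time course.

    Parameters
    ----------
    table
        DataFrame with columns ``sample_id, arm, condition, day,
        replicate``.  ``day`` counts days post-treatment; for control
        samples it records the reference collection day.

    Raises
    ------
    ValueError
        If required columns are missing, sample ids are duplicated, an
        arm lacks a control or treated samples, or a control condition
        spans multiple days.
    """

    REQUIRED = ("sample_id", "arm", "condition", "day", "replicate")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"design is missing required columns: {missing}")
        t = table.loc[:, list(self.REQUIRED)].copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["arm"] = t["arm"].astype(str)
        t["condition"] = t["condition"].astype(str)
        t["day"] = pd.to_numeric(t["day"], errors="raise")
        t["replicate"] = pd.to_numeric(t["replicate"], errors="raise").astype(int)

        dup = t["sample_id"][t["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicated sample ids in design: {sorted(set(dup))}")
        bad_arm = sorted(set(t["arm"]) - set(ARMS))
        if bad_arm:
            raise ValueError(f"unknown arm(s) {bad_arm}; expected one of {ARMS}")
        bad_cond = sorted(set(t["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ValueError(f"unknown condition(s) {bad_cond}; expected one of {CONDITIONS}")
        if (t["day"] < 0).any():
            raise ValueError("day must be non-negative")
        if (t["replicate"] < 1).any():
            raise ValueError("replicate must be a positive integer")

        for arm in ARMS:
            sub = t[t["arm"] == arm]
            if sub.empty:
                raise ValueError(f"design has no samples for arm {arm!r}")
            ctrl = sub[sub["condition"] == "control"]
            if ctrl.empty:
                raise ValueError(f"arm {arm!r} has no control samples")
            if ctrl["day"].nunique() != 1:
                raise ValueError(f"arm {arm!r} must have exactly one control condition")
            if sub[sub["condition"] == "treated"].empty:
                raise ValueError(f"arm {arm!r} has no treated samples")

        self.table = t.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def control_samples(self, arm: str) -> list[str]:
        sub = self.table
        m = (sub["arm"] == arm) & (sub["condition"] == "control")
        return list(sub.loc[m, "sample_id"])

    def control_day(self, arm: str) -> float:
        sub = self.table
        m = (sub["arm"] == arm) & (sub["condition"] == "control")
        return float(sub.loc[m, "day"].iloc[0])

    def treated_days(self, arm: str) -> list[float]:
        sub = self.table
        m = (sub["arm"] == arm) & (sub["condition"] == "treated")
        return sorted(float(d) for d in sub.loc[m, "day"].unique())

    def samples(self, arm: str, condition: str, day: float | None = None) -> list[str]:
        sub = self.table
        m = (sub["arm"] == arm) & (sub["condition"] == condition)
        if day is not None:
            m &= sub["day"] == day
        return list(sub.loc[m, "sample_id"])

    def groups(self):
        """Yield ``(arm, condition, day, sample_ids)`` for every condition group."""
        for (arm, condition, day), sub in self.table.groupby(
            ["arm", "condition", "day"], sort=True
        ):
            yield arm, condition, float(day), list(sub["sample_id"])

    def __eq__(self, other) -> bool:
        return isinstance(other, StudyDesign) and self.table.equals(other.table)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"StudyDesign({len(self.table)} samples, arms={sorted(set(self.table['arm']))})"


@dataclass
class CountMatrix:
    """Integer read counts per transcript per sample.

    ``library_sizes`` holds total mapped reads per sample, which may
    exceed the column sum (reads mapping to transcripts outside this
    matrix still count toward the library).
    """

    counts: pd.DataFrame
    lengths_nt: pd.Series
    library_sizes: pd.Series

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()]
            raise ValueError(f"duplicate transcript ids: {sorted(set(dups))[:5]}")
        self.counts.index.name = "transcript_id"
        self.lengths_nt = self.lengths_nt.reindex(self.counts.index)
        if self.lengths_nt.isna().any():
            raise ValueError("every transcript needs a length")
        if (self.lengths_nt <= 0).any():
            raise ValueError("transcript lengths must be positive")
        self.lengths_nt = self.lengths_nt.astype(int)
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.isnan(vals.astype(float)).any():
            raise ValueError("counts contain missing values")
        if not np.array_equal(vals, np.floor(vals)):
            raise ValueError("counts must be integers")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            missing = list(self.library_sizes.index[self.library_sizes.isna()])
            raise ValueError(f"missing library size for sample(s) {missing}")
        self.library_sizes = self.library_sizes.astype(np.int64)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        short = self.library_sizes < self.counts.sum(axis=0)
        if short.any():
            raise ValueError(
                "library size smaller than column sum for sample(s) "
                f"{list(self.library_sizes.index[short])}"
            )

    @property
    def transcript_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset(self, transcript_ids: Iterable[str]) -> "CountMatrix":
        ids = pd.Index(transcript_ids)
        return CountMatrix(
            counts=self.counts.loc[ids].copy(),
            lengths_nt=self.lengths_nt.loc[ids].copy(),
            library_sizes=self.library_sizes.copy(),
        )


@dataclass
class AnnotationTable:
    """Flat transcript-to-term mapping over an explicit universe."""

    mapping: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        outside = set(self.mapping) - set(self.universe)
        if outside:
            raise ValueError(
                f"annotated transcripts outside the universe: {sorted(outside)[:5]}"
            )
        empty = [t for t, terms in self.mapping.items() if not terms]
        if empty:
            raise ValueError(f"empty term sets for {empty[:5]}")

    def term_members(self) -> dict[str, set[str]]:
        """Invert the mapping: term id -> set of annotated transcripts."""
        inv: dict[str, set[str]] = {}
        for tid, terms in self.mapping.items():
            for term in terms:
                inv.setdefault(term, set()).add(tid)
        return inv

    def restrict(self, ids: Iterable[str]) -> "AnnotationTable":
        keep = set(ids) & set(self.universe)
        mapping = {t: set(v) for t, v in self.mapping.items() if t in keep}
        return AnnotationTable(mapping=mapping, universe=keep)


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def load_design(path: str | Path) -> StudyDesign:
    return StudyDesign(_read_tsv(path))


def load_dataset(
    counts_path: str | Path,
    design_path: str | Path,
    library_sizes_path: str | Path | None = None,
) -> tuple[CountMatrix, StudyDesign]:
    """Read a counts table and its matching design.

    Samples present in the counts file but absent from the design are
    dropped with a warning; a designed sample missing from the counts is
    a hard error naming the sample.
    """
    design = load_design(design_path)
    raw = _read_tsv(counts_path)
    if raw.columns[0] != "transcript_id" or raw.columns[1] != "length_nt":
        raise ValueError(
            "counts file must start with 'transcript_id' and 'length_nt' columns, "
            f"got {list(raw.columns[:2])}"
        )
    raw["transcript_id"] = raw["transcript_id"].astype(str)
    dup = raw["transcript_id"][raw["transcript_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate transcript_id in counts: {sorted(set(dup))[:5]}")
    raw = raw.set_index("transcript_id")
    lengths = raw["length_nt"]
    counts = raw.drop(columns=["length_nt"])

    missing = [s for s in design.sample_ids if s not in counts.columns]
    if missing:
        raise ValueError(f"designed sample(s) missing from counts file: {missing}")
    extra = [c for c in counts.columns if c not in design.sample_ids]
    if extra:
        warnings.warn(
            f"dropping {len(extra)} count column(s) not in the design: {extra}",
            stacklevel=2,
        )
        counts = counts.drop(columns=extra)
    counts = counts.loc[:, design.sample_ids]

    if library_sizes_path is not None:
        lib = _read_tsv(library_sizes_path)
        library_sizes = pd.Series(
            {str(c): int(lib[c].iloc[0]) for c in lib.columns}, name="library_size"
        )
    else:
        warnings.warn(
            "no library-size table given; falling back to column sums",
            stacklevel=2,
        )
        library_sizes = counts.sum(axis=0)
    cm = CountMatrix(counts=counts, lengths_nt=lengths, library_sizes=library_sizes)
    logger.info(
        "loaded %d transcripts x %d samples", len(cm.transcript_ids), len(cm.sample_ids)
    )
    return cm, design


def load_annotations(path: str | Path, universe: Iterable[str]) -> AnnotationTable:
    """Read ``transcript_id <tab> term_id`` pairs, restricted to ``universe``.

    Duplicate pairs collapse to one; pairs outside the universe are
    dropped silently (the annotation may cover a larger transcriptome).
    A malformed line is a hard error with its line number.
    """
    universe = set(str(u) for u in universe)
    mapping: dict[str, set[str]] = {}
    n_pairs = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["transcript_id", "term_id"]:
                continue  # optional header
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"malformed annotation line {lineno} in {path}: {line!r}"
                )
            n_pairs += 1
            tid, term = fields
            if tid in universe:
                mapping.setdefault(tid, set()).add(term)
    if n_pairs == 0:
        warnings.warn(f"annotation file {path} contains no pairs", stacklevel=2)
    return AnnotationTable(mapping=mapping, universe=universe)


# ---------------------------------------------------------------------------
# writers


def _order_rows(table: pd.DataFrame) -> pd.DataFrame:
    if table.index.name == "transcript_id":
        return table.sort_index()
    if "transcript_id" in table.columns:
        return table.sort_values("transcript_id", kind="mergesort")
    return table


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Write one headered TSV per named table plus an optional run manifest.

    Rows are ordered by transcript id where applicable, so repeated runs
    on identical inputs are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        ordered = _order_rows(table)
        ordered.to_csv(
            path,
            sep="\t",
            index=ordered.index.name is not None,
            lineterminator="\n",
        )
        paths[name] = path
    if manifest is not None:
        path = out_dir / "run_manifest.yaml"
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dict(manifest), fh, sort_keys=False)
        paths["run_manifest"] = path
    return paths


def write_dataset(
    cm: CountMatrix, design: StudyDesign, out_dir: str | Path
) -> dict[str, Path]:
    """Write counts, library sizes, and design in the formats load_dataset reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts_path = out_dir / "counts.tsv"
    table = cm.counts.copy()
    table.insert(0, "length_nt", cm.lengths_nt)
    table.to_csv(counts_path, sep="\t", lineterminator="\n")
    lib_path = out_dir / "library_sizes.tsv"
    with open(lib_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cm.library_sizes.index) + "\n")
        fh.write("\t".join(str(int(v)) for v in cm.library_sizes) + "\n")
    design_path = out_dir / "design.tsv"
    design.table.to_csv(design_path, sep="\t", index=False, lineterminator="\n")
    return {"counts": counts_path, "library_sizes": lib_path, "design": design_path}
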