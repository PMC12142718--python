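"""Known-lifespan aggregation and the species x promoter feature matrix.

Reported lifespans (longevity / maximum age, t_max) vary between sources;
the label used for modelling is the per-species mean (optionally median) of
all reports, in years.  Labels are natural-log transformed for the linear
model.  The feature matrix holds promoter CpG O/E values with 0 encoding
the absence of a homology hit, so it never has missing entries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LifespanRecord:
    species: str
    reported_lifespan: float  # years, > 0
    source: str = ""

    def __post_init__(self) -> None:
        if not self.reported_lifespan > 0:
            raise ValueError(
                f"{self.species}: reported lifespan must be positive "
                f"(got {self.reported_lifespan}); the log transform requires it"
            )


@dataclass
class FeatureTable:
    """Row-aligned species x promoter O/E matrix with lifespan labels."""

    species_ids: list[str]
    promoter_ids: list[str]
    matrix: np.ndarray  # (n_species, n_promoters), >= 0, no missing entries
    known_lifespan: np.ndarray  # years
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.known_lifespan = np.asarray(self.known_lifespan, dtype=float)
        n, p = self.matrix.shape
        if len(self.species_ids) != n or len(self.promoter_ids) != p:
            raise ValueError("matrix shape does not match id lists")
        if len(set(self.species_ids)) != n:
            raise ValueError("species_ids must be unique")
        if self.known_lifespan.shape != (n,):
            raise ValueError("known_lifespan length mismatch")
        if np.any(self.known_lifespan <= 0):
            raise ValueError("known lifespans must be positive")
        if np.any(~np.isfinite(self.matrix)) or np.any(self.matrix < 0):
            raise ValueError("matrix entries must be finite and >= 0")

    @property
    def log_lifespan(self) -> np.ndarray:
        return np.log(self.known_lifespan)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def zero_rows(self) -> list[str]:
        """Species whose entire feature row is 0 (no homology hits at all)."""
        mask = ~self.matrix.any(axis=1)
        return [s for s, z in zip(self.species_ids, mask) if z]

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        df = pd.DataFrame(
            self.matrix, index=self.species_ids, columns=self.promoter_ids
        )
        df.insert(0, "known_lifespan", self.known_lifespan)
        df.to_csv(path, sep="\t", index_label="species")
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump(
                    {"promoter_ids": self.promoter_ids, "n_species": self.n_species},
                    fh,
                    indent=2,
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col="species")
        labels = df.pop("known_lifespan").to_numpy()
        return cls(
            species_ids=list(df.index),
            promoter_ids=list(df.columns),
            matrix=df.to_numpy(dtype=float),
            known_lifespan=labels,
        )


def aggregate_known_lifespan(
    records: Sequence[LifespanRecord], method: str = "mean"
) -> pd.DataFrame:
    """Collapse reported lifespans to one label per species.

    Returns a DataFrame indexed by species with columns ``known_lifespan``
    (mean or median of reports, years), ``sd`` (sample standard deviation,
    0 for a single report) and ``n_reports``.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")
    if not records:
        raise ValueError("no lifespan records supplied")
    df = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "value": [r.reported_lifespan for r in records],
        }
    )
    grouped = df.groupby("species", sort=True)["value"]
    agg = grouped.mean() if method == "mean" else grouped.median()
    out = pd.DataFrame(
        {
            "known_lifespan": agg,
            "sd": grouped.std(ddof=1).fillna(0.0),
            "n_reports": grouped.count(),
        }
    )
    return out


def read_lifespan_tsv(path: str | Path) -> list[LifespanRecord]:
    """Read a reported-lifespan table: species, reported_lifespan, source."""
    df = pd.read_csv(path, sep="\t")
    required = {"species", "reported_lifespan"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        LifespanRecord(
            species=str(row.species).strip(),
            reported_lifespan=float(row.reported_lifespan),
            source=str(getattr(row, "source", "")),
        )
        for row in df.itertuples()
    ]


def build_feature_table(
    oe_vectors: Mapping[str, np.ndarray],
    labels: Mapping[str, float],
    promoter_ids: Sequence[str],
    metadata: pd.DataFrame | None = None,
) -> tuple[FeatureTable, list[str]]:
    """Assemble the row-aligned table from per-genome O/E vectors and labels.

    Species present on only one side are excluded and listed in the returned
    reconciliation report.  Species names are matched exactly after
    trimming and case-folding.  All-zero rows are retained: a zero-hit
    genome is a data-quality failure flagged at prediction time, not a
    modelling exclusion rule here.
    """

    def norm(s: str) -> str:
        return s.strip().casefold()

    oe_by_norm: dict[str, tuple[str, np.ndarray]] = {}
    for sp, vec in oe_vectors.items():
        key = norm(sp)
        if key in oe_by_norm:
            raise ValueError(f"duplicated species row {sp!r}")
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(promoter_ids),):
            raise ValueError(
                f"{sp}: O/E vector length {vec.shape} does not match "
                f"{len(promoter_ids)} promoters"
            )
        oe_by_norm[key] = (sp, vec)
    labels_by_norm = {norm(sp): (sp, v) for sp, v in labels.items()}

    reconciliation: list[str] = []
    species_ids: list[str] = []
    rows: list[np.ndarray] = []
    y: list[float] = []
    for key, (sp, vec) in oe_by_norm.items():
        if key not in labels_by_norm:
            reconciliation.append(f"{sp}: genome present, no lifespan label")
            continue
        species_ids.append(sp)
        rows.append(vec)
        y.append(labels_by_norm[key][1])
    for key, (sp, _) in labels_by_norm.items():
        if key not in oe_by_norm:
            reconciliation.append(f"{sp}: lifespan label present, no genome")
    for msg in reconciliation:
        logger.warning("reconciliation: %s", msg)

    table = FeatureTable(
        species_ids=species_ids,
        promoter_ids=list(promoter_ids),
        matrix=np.vstack(rows) if rows else np.empty((0, len(promoter_ids))),
        known_lifespan=np.asarray(y),
        metadata=metadata,
    )
    return table, reconciliation


def filter_by_completeness(
    table: FeatureTable, min_completeness: float = 10.0
) -> FeatureTable:
    """Optional assembly-quality filter (off by default in pipelines).

    Drops species whose metadata ``completeness`` (busco-style percentage,
    pass-through only — never computed here) falls below the threshold.
    A low-stringency cutoff (around 10%) is enough to catch fragmentary
    metagenome-derived assemblies while keeping ordinary drafts.
    """
    if table.metadata is None or "completeness" not in table.metadata.columns:
        return table
    comp = table.metadata.reindex(table.species_ids)["completeness"]
    keep = [
        i
        for i, sp in enumerate(table.species_ids)
        if pd.isna(comp.iloc[i]) or comp.iloc[i] >= min_completeness
    ]
    return FeatureTable(
        species_ids=[table.species_ids[i] for i in keep],
        promoter_ids=table.promoter_ids,
        matrix=table.matrix[keep],
        known_lifespan=table.known_lifespan[keep],
        metadata=table.metadata,
    )
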