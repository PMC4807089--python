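"""Presence/absence matrices and prevalence / persistence summaries.

Detections (metagenomic: >= 1 read assigned to a phylotype in a
specimen; RT-PCR: amplicon-positive) are tabulated into a phylotype x
specimen boolean matrix joined to specimen metadata (animal, site, time
point).  Summaries count specimens positive for at least one / at least
two phylotypes, and persistence counts animals positive for a given
phylotype at one or at two or more distinct time points.  Time points
are categorical labels, not numbers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .identity import IdentityMatrix

EVIDENCE_KINDS = ("metagenomic", "rtpcr")


@dataclass(frozen=True)
class Specimen:
    specimen_id: str
    animal_id: str
    site: str
    time_point: str


@dataclass(frozen=True)
class Detection:
    specimen_id: str
    animal_id: str
    site: str
    time_point: str
    phylotype: str
    evidence: str = "metagenomic"
    n_reads: int | None = None

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_KINDS:
            raise ValueError(f"unknown evidence kind {self.evidence!r}")
        if self.evidence == "metagenomic" and (self.n_reads is None or self.n_reads < 1):
            raise ValueError("metagenomic detection requires n_reads >= 1")


@dataclass
class PresenceMatrix:
    """Boolean phylotype x specimen grid plus specimen metadata."""

    grid: pd.DataFrame            # index: phylotypes, columns: specimen ids
    metadata: pd.DataFrame        # index: specimen ids

    @property
    def phylotypes(self) -> list[str]:
        return list(self.grid.index)

    @property
    def specimens(self) -> list[str]:
        return list(self.grid.columns)

    def to_tsv(self, path) -> None:
        out = self.grid.astype(int)
        out.to_csv(path, sep="\t", index_label="phylotype")

    @classmethod
    def from_tsv(cls, path, metadata: pd.DataFrame | None = None) -> "PresenceMatrix":
        grid = pd.read_csv(path, sep="\t", index_col="phylotype").astype(bool)
        if metadata is None:
            metadata = pd.DataFrame(index=grid.columns)
        return cls(grid=grid, metadata=metadata)


def build_presence_matrix(
    detections: Sequence[Detection],
    specimens: Sequence[Specimen] | None = None,
    phylotypes: Sequence[str] | None = None,
    evidence: str | None = None,
) -> PresenceMatrix:
    """Presence matrix with deterministic ordering (phylotype name, then
    specimen id).  ``specimens`` lists the full specimen panel including
    negatives; detections referencing unknown specimens raise with the
    offending ids.  ``evidence`` restricts to one evidence kind."""
    if evidence is not None:
        detections = [d for d in detections if d.evidence == evidence]
    if specimens is None:
        seen: dict[str, Specimen] = {}
        for d in detections:
            seen.setdefault(
                d.specimen_id, Specimen(d.specimen_id, d.animal_id, d.site, d.time_point)
            )
        specimens = list(seen.values())
    known = {s.specimen_id for s in specimens}
    unknown = sorted({d.specimen_id for d in detections} - known)
    if unknown:
        raise ValueError(f"detections reference unknown specimens: {unknown}")

    pts = sorted(phylotypes or {d.phylotype for d in detections})
    cols = sorted(known)
    grid = pd.DataFrame(False, index=pts, columns=cols)
    for d in detections:
        if d.phylotype in grid.index:
            grid.loc[d.phylotype, d.specimen_id] = True
    meta = pd.DataFrame(
        [
            {"animal_id": s.animal_id, "site": s.site, "time_point": s.time_point}
            for s in sorted(specimens, key=lambda s: s.specimen_id)
        ],
        index=sorted(known),
    )
    return PresenceMatrix(grid=grid, metadata=meta)


def summarize_prevalence(m: PresenceMatrix) -> dict:
    """Specimen counts positive for >=1 and >=2 phylotypes plus
    per-phylotype specimen counts."""
    if m.grid.size == 0:
        raise ValueError("empty presence matrix")
    per_specimen = m.grid.sum(axis=0)
    return {
        "n_specimens": int(m.grid.shape[1]),
        "n_specimens_ge1": int((per_specimen >= 1).sum()),
        "n_specimens_ge2": int((per_specimen >= 2).sum()),
        "per_phylotype": {pt: int(c) for pt, c in m.grid.sum(axis=1).items()},
    }


def persistence(detections: Sequence[Detection], phylotype: str) -> dict:
    """Animals positive for ``phylotype`` at >=1 and at >=2 distinct time
    points."""
    relevant = [d for d in detections if d.phylotype == phylotype]
    if not relevant:
        raise ValueError(f"phylotype {phylotype!r} has no detections")
    by_animal: dict[str, set[str]] = {}
    for d in relevant:
        by_animal.setdefault(d.animal_id, set()).add(d.time_point)
    return {
        "n_animals_positive_any": len(by_animal),
        "n_animals_positive_both_timepoints": sum(
            len(tps) >= 2 for tps in by_animal.values()
        ),
    }


def site_partition_check(
    matrix: IdentityMatrix, site_labels: Mapping[str, str]
) -> tuple[bool, float, float]:
    """Do sites form clean identity clusters?

    True when the minimum within-site identity exceeds the maximum
    between-site identity; also returns the mean within- and between-site
    identities.  Sites with a single sequence contribute no within-site
    pairs and are excluded from the within mean with a warning.
    """
    names = matrix.names
    sites = {nm: site_labels[nm] for nm in names}
    if len(set(sites.values())) < 2:
        raise ValueError("need at least two sites")
    singletons = [
        s for s in set(sites.values())
        if sum(v == s for v in sites.values()) == 1
    ]
    if singletons:
        warnings.warn(f"sites with a single sequence excluded from within-mean: {singletons}")
    within, between = [], []
    n = len(names)
    for i in range(n):
        for j in range(i + 1, n):
            val = float(matrix.identity[i, j])
            (within if sites[names[i]] == sites[names[j]] else between).append(val)
    if not within or not between:
        raise ValueError("need within-site and between-site pairs")
    ok = min(within) > max(between)
    return ok, float(np.mean(within)), float(np.mean(between))


# ---------------------------------------------------------------------------
# TSV interchange


def read_detections_tsv(path) -> list[Detection]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        n_reads = row.get("n_reads")
        out.append(
            Detection(
                specimen_id=row["specimen_id"],
                animal_id=row["animal_id"],
                site=row["site"],
                time_point=str(row["time_point"]),
                phylotype=row["phylotype"],
                evidence=row.get("evidence", "metagenomic"),
                n_reads=int(n_reads) if n_reads not in (None, "", "NA") else None,
            )
        )
    return out


def read_specimens_tsv(path) -> list[Specimen]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        Specimen(row["specimen_id"], row["animal_id"], row["site"], str(row["time_point"]))
        for _, row in df.iterrows()
    ]


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
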