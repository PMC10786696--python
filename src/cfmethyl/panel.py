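"""Tissue-specific methylation marker panel: types, I/O, validation.

A marker is a short amplicon whose CpG sites are unmethylated only in one
cell type, so a sequenced molecule that is unmethylated at every CpG of the
amplicon can be assigned to that cell type with high specificity. A panel
bundles markers for the solid tissues commonly damaged in chronic
graft-versus-host disease (liver, skin, lung, gastrointestinal epithelium)
and for the immune cell types whose turnover the assay tracks.

Coordinates are 0-based half-open (BED convention). The on-disk format is a
TSV with one marker per row and a comma-joined list of CpG offsets relative
to the amplicon start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

CELLTYPES = (
    "liver",
    "skin",
    "lung",
    "gi",
    "neutrophil",
    "monocyte",
    "eosinophil",
    "b_cell",
    "t_cell",
    "cd8_t",
    "treg",
)

#: solid-tissue cell types with an NIH organ score attached
SOLID_TISSUES = ("liver", "skin", "lung", "gi")

_COLUMNS = ("marker_id", "chrom", "start", "end", "strand", "target_celltype", "cpg_offsets")


class PanelError(ValueError):
    """Malformed or invalid panel definition."""


@dataclass(frozen=True)
class MarkerLocus:
    """One amplicon locus with its CpG positions and target cell type.

    ``cpg_offsets`` are the offsets of the C of each CpG dinucleotide
    relative to ``start``; they must be strictly increasing, lie inside the
    amplicon, and number at least two — assignment relies on molecules
    carrying multiple concordant CpG calls.
    """

    marker_id: str
    chrom: str
    start: int
    end: int
    cpg_offsets: tuple[int, ...]
    target_celltype: str
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpg_offsets", tuple(int(o) for o in self.cpg_offsets))
        if self.end <= self.start:
            raise PanelError(f"{self.marker_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise PanelError(f"{self.marker_id}: strand must be + or -")
        if self.target_celltype not in CELLTYPES:
            raise PanelError(
                f"{self.marker_id}: unknown cell type {self.target_celltype!r}"
            )
        offs = self.cpg_offsets
        if len(offs) < 2:
            raise PanelError(f"{self.marker_id}: needs >=2 CpG sites, got {len(offs)}")
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise PanelError(f"{self.marker_id}: cpg_offsets not strictly increasing")
        if offs[0] < 0 or offs[-1] >= self.end - self.start:
            raise PanelError(f"{self.marker_id}: cpg_offsets outside amplicon span")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)


@dataclass
class MarkerPanel:
    """An ordered collection of marker loci, validated on construction."""

    loci: list[MarkerLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.loci:
            raise PanelError("panel has no loci")
        seen_ids: set[str] = set()
        seen_spans: set[tuple[str, int, int]] = set()
        for locus in self.loci:
            if locus.marker_id in seen_ids:
                raise PanelError(f"duplicate marker_id {locus.marker_id!r}")
            seen_ids.add(locus.marker_id)
            span = (locus.chrom, locus.start, locus.end)
            if span in seen_spans:
                raise PanelError(f"duplicate span {span} ({locus.marker_id})")
            seen_spans.add(span)

    @property
    def celltypes(self) -> tuple[str, ...]:
        """Target cell types present, in canonical order."""
        present = {l.target_celltype for l in self.loci}
        return tuple(ct for ct in CELLTYPES if ct in present)

    def loci_for(self, celltype: str) -> list[MarkerLocus]:
        return [l for l in self.loci if l.target_celltype == celltype]

    def __len__(self) -> int:
        return len(self.loci)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerPanel):
            return NotImplemented
        return self.loci == other.loci

    def __getitem__(self, marker_id: str) -> MarkerLocus:
        for locus in self.loci:
            if locus.marker_id == marker_id:
                return locus
        raise KeyError(marker_id)


def load_panel(path: str | Path) -> MarkerPanel:
    """Read a marker panel from its TSV definition file.

    Raises :class:`PanelError` naming the offending line for malformed rows
    and for any invariant violation (duplicate ids, <2 CpGs, non-increasing
    offsets, ...).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise PanelError(f"{path}: empty panel file")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != _COLUMNS:
        raise PanelError(f"{path}: bad header {header!r}, expected {_COLUMNS!r}")
    loci = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(_COLUMNS):
            raise PanelError(f"{path}:{lineno}: expected {len(_COLUMNS)} fields, got {len(fields)}")
        marker_id, chrom, start, end, strand, celltype, offsets = fields
        try:
            locus = MarkerLocus(
                marker_id=marker_id,
                chrom=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
                target_celltype=celltype,
                cpg_offsets=tuple(int(o) for o in offsets.split(",")),
            )
        except PanelError as exc:
            raise PanelError(f"{path}:{lineno}: {exc}") from exc
        except ValueError as exc:
            raise PanelError(f"{path}:{lineno}: malformed field ({exc})") from exc
        loci.append(locus)
    if not loci:
        raise PanelError(f"{path}: no marker rows")
    return MarkerPanel(loci)


def write_panel(panel: MarkerPanel, path: str | Path) -> Path:
    """Write ``panel`` as TSV such that :func:`load_panel` round-trips it."""
    path = Path(path)
    rows = ["\t".join(_COLUMNS)]
    for l in panel.loci:
        rows.append(
            "\t".join(
                [
                    l.marker_id,
                    l.chrom,
                    str(l.start),
                    str(l.end),
                    l.strand,
                    l.target_celltype,
                    ",".join(str(o) for o in l.cpg_offsets),
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path


def write_bed(panel: MarkerPanel, path: str | Path) -> Path:
    """Export marker spans as 6-column BED (no CpG detail)."""
    path = Path(path)
    rows = [
        f"{l.chrom}\t{l.start}\t{l.end}\t{l.marker_id}\t0\t{l.strand}" for l in panel.loci
    ]
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path


# -- fixture panel -----------------------------------------------------------

#: markers per cell type in the default panel. Solid-tissue counts follow the
#: assay design (5 liver, 5 skin, 10 lung, 8 GI); immune cell types get 4 each.
DEFAULT_MARKER_COUNTS: dict[str, int] = {
    "liver": 5,
    "skin": 5,
    "lung": 10,
    "gi": 8,
    "neutrophil": 4,
    "monocyte": 4,
    "eosinophil": 4,
    "b_cell": 4,
    "t_cell": 4,
    "cd8_t": 4,
    "treg": 4,
}

_AMPLICON_LEN = 120


def default_panel(counts: dict[str, int] | None = None) -> MarkerPanel:
    """Build the deterministic fixture panel.

    Coordinates and CpG layouts are synthetic but fixed: the same panel is
    produced on every call, so downstream results are reproducible without
    shipping a data file.
    """
    import numpy as np

    counts = dict(DEFAULT_MARKER_COUNTS if counts is None else counts)
    rng = np.random.default_rng(20140101)  # fixed: panel identity, not a knob
    loci = []
    chrom_cycle = [f"chr{i}" for i in range(1, 23)]
    pos = 1_000_000
    i_chrom = 0
    for celltype in CELLTYPES:
        n = counts.get(celltype, 0)
        for k in range(n):
            n_cpg = int(rng.integers(4, 7))  # 4-6 CpGs per amplicon
            offs = np.sort(rng.choice(np.arange(10, _AMPLICON_LEN - 10, 3), size=n_cpg, replace=False))
            loci.append(
                MarkerLocus(
                    marker_id=f"{celltype}_{k + 1:02d}",
                    chrom=chrom_cycle[i_chrom % len(chrom_cycle)],
                    start=pos,
                    end=pos + _AMPLICON_LEN,
                    cpg_offsets=tuple(int(o) for o in offs),
                    target_celltype=celltype,
                )
            )
            i_chrom += 1
            pos += 10_000
    return MarkerPanel(loci)
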