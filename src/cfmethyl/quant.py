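"""From bisulfite amplicon reads to tissue-specific cfDNA quantities.

The chain is: per-read methylation pattern calling at each marker locus →
per-marker unmethylated-molecule fraction → per-cell-type fraction (mean over
that cell type's markers) → absolute concentration in genome equivalents per
mL plasma (fraction × total cfDNA × GE per ng). A spike-in detection-limit
assay estimates the smallest tissue fraction the panel reliably detects.

Conventions: after bisulfite conversion a T at a CpG-C position means the
cytosine was unmethylated, a C means it was methylated (protected). Cytosines
outside CpG context are unmethylated in genomic DNA, so residual Cs there
flag incomplete conversion; molecules exceeding the conversion-failure
threshold are excluded from counting, not silently dropped from output.
Undefined fractions propagate as NaN, never as zero — zero is a biological
claim about the sample, NaN is an assay failure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import MarkerLocus, MarkerPanel
from .synthetic import BACKGROUND, locus_reference, noncpg_c_positions

#: mass of one haploid human genome, picograms (1 ng ~ 303 genome equivalents)
MASS_PG_PER_HAPLOID_GENOME = 3.3

UNMETH, METH, MISSING = "U", "M", "."


@dataclass
class QuantConfig:
    """Quality-control and counting parameters.

    ``rule`` is the unmethylated-molecule rule: ``"all"`` requires every
    observed CpG unmethylated (maximal specificity, the default); an integer
    *k* requires at least *k* unmethylated calls.
    """

    conversion_fail_threshold: float = 0.1  # max fraction of non-CpG Cs still C
    missing_cap: float = 0.2  # max fraction of missing CpG calls per molecule
    rule: int | str = "all"
    ge_mass_pg: float = MASS_PG_PER_HAPLOID_GENOME


@dataclass(frozen=True)
class MoleculePattern:
    """Per-CpG methylation calls of one sequenced molecule at one locus."""

    marker_id: str
    molecule_id: str
    calls: str  # one of U/M/. per CpG of the locus
    conversion_ok: bool

    @property
    def n_observed(self) -> int:
        return len(self.calls) - self.calls.count(MISSING)

    @property
    def n_unmethylated(self) -> int:
        return self.calls.count(UNMETH)

    @property
    def missing_fraction(self) -> float:
        return self.calls.count(MISSING) / len(self.calls)

    def qc_pass(self, config: QuantConfig) -> bool:
        return (
            self.conversion_ok
            and self.n_observed > 0
            and self.missing_fraction <= config.missing_cap
        )


@dataclass(frozen=True)
class MarkerCount:
    """QC-passing molecule counts at one marker."""

    marker_id: str
    n_total: int
    n_unmethylated: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_unmethylated <= self.n_total:
            raise ValueError("need 0 <= n_unmethylated <= n_total")

    @property
    def fraction(self) -> float:
        """Unmethylated-molecule fraction; NaN when no molecule passed QC."""
        return self.n_unmethylated / self.n_total if self.n_total else float("nan")


@dataclass
class TissueProfile:
    """Per-cell-type unmethylated fraction and absolute concentration."""

    fractions: dict[str, float]
    ge_per_ml: dict[str, float]
    total_cfdna_ng_per_ml: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "celltype": list(self.fractions),
                "fraction": [self.fractions[c] for c in self.fractions],
                "ge_per_ml": [self.ge_per_ml[c] for c in self.fractions],
            }
        )


# -- pattern calling ---------------------------------------------------------

def call_molecule_patterns(
    reads: Iterable[tuple[str, str]],
    locus: MarkerLocus,
    reference: str | None = None,
    config: QuantConfig | None = None,
) -> list[MoleculePattern]:
    """Call per-CpG methylation for reads assigned to ``locus``.

    ``reads`` are ``(name, sequence)`` pairs positioned at the amplicon start.
    At each CpG-C offset: T → unmethylated, C → methylated, anything else →
    missing. ``conversion_ok`` is False when more than the configured
    threshold of non-CpG reference cytosines still read C (failed bisulfite
    conversion); such molecules are flagged here and excluded later by
    :meth:`MoleculePattern.qc_pass`. Reads shorter than the amplicon yield
    all-missing patterns rather than an error.
    """
    config = config or QuantConfig()
    ref = reference if reference is not None else locus_reference(locus)
    nonc = noncpg_c_positions(locus, ref)
    patterns = []
    for name, seq in reads:
        if len(seq) < locus.length:
            patterns.append(MoleculePattern(locus.marker_id, name, MISSING * locus.n_cpgs, False))
            continue
        calls = []
        for off in locus.cpg_offsets:
            base = seq[off]
            calls.append(UNMETH if base == "T" else METH if base == "C" else MISSING)
        if len(nonc):
            unconverted = sum(1 for i in nonc if seq[i] == "C") / len(nonc)
            conversion_ok = unconverted <= config.conversion_fail_threshold
        else:
            conversion_ok = True
        patterns.append(MoleculePattern(locus.marker_id, name, "".join(calls), conversion_ok))
    return patterns


def unmethylated_fraction(
    patterns: Sequence[MoleculePattern],
    config: QuantConfig | None = None,
) -> MarkerCount:
    """Count QC-passing molecules meeting the unmethylated-molecule rule.

    With the default ``rule="all"`` a molecule counts when every observed CpG
    is unmethylated; with integer *k*, when at least *k* are.
    """
    config = config or QuantConfig()
    if not patterns:
        return MarkerCount("", 0, 0)
    marker_id = patterns[0].marker_id
    n_total = n_unmeth = 0
    for p in patterns:
        if not p.qc_pass(config):
            continue
        n_total += 1
        threshold = p.n_observed if config.rule == "all" else int(config.rule)
        if p.n_unmethylated >= threshold:
            n_unmeth += 1
    return MarkerCount(marker_id, n_total, n_unmeth)


def tissue_fraction(
    marker_fractions: dict[str, float], panel: MarkerPanel
) -> dict[str, float]:
    """Average each cell type's marker fractions (unweighted, NaN-skipping).

    A cell type whose markers are all missing gets NaN.
    """
    out = {}
    for celltype in panel.celltypes:
        vals = [
            marker_fractions[l.marker_id]
            for l in panel.loci_for(celltype)
            if l.marker_id in marker_fractions and not math.isnan(marker_fractions[l.marker_id])
        ]
        out[celltype] = float(np.mean(vals)) if vals else float("nan")
    return out


def absolute_concentration(
    fraction: float,
    total_cfdna_ng_per_ml: float,
    ge_mass_pg: float = MASS_PG_PER_HAPLOID_GENOME,
) -> float:
    """Convert a tissue fraction to genome equivalents per mL plasma.

    GE/mL = fraction × total cfDNA (ng/mL) × 1000 (pg/ng) / mass per genome (pg).
    NaN fractions propagate.
    """
    if math.isnan(fraction):
        return float("nan")
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if total_cfdna_ng_per_ml < 0:
        raise ValueError("total cfDNA must be >= 0")
    return fraction * total_cfdna_ng_per_ml * 1000.0 / ge_mass_pg


# -- read assignment and the full sample pipeline ----------------------------

def _matches_reference(seq: str, ref: str, n: int = 15) -> bool:
    # bisulfite-aware prefix comparison: a reference C may read C or T
    if len(seq) < n:
        return False
    return all(r == s or (r == "C" and s == "T") for r, s in zip(ref[:n], seq[:n]))


def assign_reads(
    reads: Iterable[tuple[str, str]], panel: MarkerPanel
) -> dict[str, list[tuple[str, str]]]:
    """Group reads by marker: by read-name tag, else by 15-base prefix match."""
    refs = {l.marker_id: locus_reference(l) for l in panel.loci}
    buckets: dict[str, list[tuple[str, str]]] = {l.marker_id: [] for l in panel.loci}
    for name, seq in reads:
        tag = name.split(":", 1)[0]
        if tag in buckets:
            buckets[tag].append((name, seq))
            continue
        for marker_id, ref in refs.items():
            if _matches_reference(seq, ref):
                buckets[marker_id].append((name, seq))
                break
    return buckets


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Load reads as (name, sequence) pairs from a FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        return [(title.split()[0], seq) for title, seq, _ in FastqGeneralIterator(fh)]


def quantify(
    reads: Iterable[tuple[str, str]] | str | Path,
    panel: MarkerPanel,
    total_cfdna_ng_per_ml: float,
    config: QuantConfig | None = None,
) -> tuple[TissueProfile, pd.DataFrame]:
    """Run the full quantification for one sample.

    ``reads`` may be a FASTQ path or in-memory ``(name, sequence)`` pairs.
    Returns the per-cell-type :class:`TissueProfile` and a per-marker count
    table (marker_id, celltype, n_total, n_unmethylated, fraction).
    """
    config = config or QuantConfig()
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    buckets = assign_reads(reads, panel)
    rows = []
    marker_fractions = {}
    for locus in panel.loci:
        patterns = call_molecule_patterns(buckets[locus.marker_id], locus, config=config)
        count = unmethylated_fraction(patterns, config)
        marker_fractions[locus.marker_id] = count.fraction
        rows.append(
            {
                "marker_id": locus.marker_id,
                "celltype": locus.target_celltype,
                "n_total": count.n_total,
                "n_unmethylated": count.n_unmethylated,
                "fraction": count.fraction,
            }
        )
    fractions = tissue_fraction(marker_fractions, panel)
    ge = {
        ct: absolute_concentration(fr, total_cfdna_ng_per_ml, config.ge_mass_pg)
        for ct, fr in fractions.items()
    }
    profile = TissueProfile(fractions, ge, total_cfdna_ng_per_ml)
    return profile, pd.DataFrame(rows)


# -- pattern TSV round trip --------------------------------------------------

def write_patterns(patterns: Sequence[MoleculePattern], path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "marker_id": [p.marker_id for p in patterns],
            "molecule_id": [p.molecule_id for p in patterns],
            "calls": [p.calls for p in patterns],
            "conversion_ok": [int(p.conversion_ok) for p in patterns],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_patterns(path: str | Path) -> list[MoleculePattern]:
    df = pd.read_csv(path, sep="\t", dtype={"calls": str})
    return [
        MoleculePattern(r.marker_id, str(r.molecule_id), r.calls, bool(r.conversion_ok))
        for r in df.itertuples()
    ]


# -- spike-in detection limit ------------------------------------------------

@dataclass
class DetectionLimitResult:
    """Outcome of the spike-in limit-of-detection simulation."""

    limit: float  # smallest grid fraction detected in >=95% of replicates (NaN if none)
    rate_table: pd.DataFrame  # columns: fraction, detection_rate
    false_detection_rate: float  # null replicates called detected (expect ~alpha)
    slope: float  # linear fit of mean estimate vs true fraction
    alpha: float
    reads_per_marker: int
    replicates: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "limit": None if math.isnan(self.limit) else self.limit,
            "alpha": self.alpha,
            "false_detection_rate": self.false_detection_rate,
            "linearity_slope": self.slope,
            "reads_per_marker": self.reads_per_marker,
            "replicates": self.replicates,
            "rates": self.rate_table.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _pass_probability(n_cpgs: int, p_unmeth_call: float, rule: int | str) -> float:
    """P(a molecule meets the unmethylated rule) given per-CpG call prob."""
    if rule == "all":
        return p_unmeth_call**n_cpgs
    return float(sps.binom.sf(int(rule) - 1, n_cpgs, p_unmeth_call))


def simulate_tissue_estimates(
    loci: Sequence[MarkerLocus],
    fraction: float,
    reads_per_marker: int,
    n_replicates: int,
    rng: np.random.Generator,
    bisulfite_failure_rate: float = 0.005,
    inappropriate_conversion_rate: float = 0.005,
    rule: int | str = "all",
) -> np.ndarray:
    """Simulate replicate tissue-fraction estimates at one spike-in fraction.

    Works at the molecule-count level: for each marker the number of
    molecules meeting the unmethylated rule is binomial with success
    probability ``f·(1−bf)^C + (1−f)·ic^C`` (C = CpGs of that marker), which
    is exactly the distribution the read-level pipeline induces under the
    all-or-none methylation model. The estimate is the mean marker fraction.
    """
    est = np.zeros(n_replicates)
    for locus in loci:
        p_target = _pass_probability(locus.n_cpgs, 1 - bisulfite_failure_rate, rule)
        p_bg = _pass_probability(locus.n_cpgs, inappropriate_conversion_rate, rule)
        p = fraction * p_target + (1 - fraction) * p_bg
        est += rng.binomial(reads_per_marker, p, size=n_replicates) / reads_per_marker
    return est / len(loci)


def detection_limit(
    panel: MarkerPanel,
    celltype: str,
    grid: Sequence[float],
    reads_per_marker: int = 10_000,
    replicates: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    bisulfite_failure_rate: float = 0.005,
    inappropriate_conversion_rate: float = 0.005,
    rule: int | str = "all",
) -> DetectionLimitResult:
    """Smallest spike-in fraction of ``celltype`` DNA robustly detected.

    For each fraction in ``grid`` (ascending, as proportions), simulates
    ``replicates`` mixtures into a fully methylated leukocyte background plus
    matched 0% controls. A replicate is "detected" when its one-sided rank
    p-value against the control distribution is ≤ ``alpha``; ranks are
    randomized across ties (conditional Monte Carlo), which makes the null
    false-detection rate exactly ``alpha`` even when controls are degenerate.
    The limit is the smallest fraction with detection rate ≥ 0.95.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty fraction grid")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be sorted ascending")
    if replicates < 20:
        raise ValueError("need >= 20 replicates")
    loci = panel.loci_for(celltype)
    if not loci:
        raise ValueError(f"panel has no markers for {celltype!r}")
    rng = np.random.default_rng(seed)

    def sim(fraction: float, n: int) -> np.ndarray:
        return simulate_tissue_estimates(
            loci,
            fraction,
            reads_per_marker,
            n,
            rng,
            bisulfite_failure_rate,
            inappropriate_conversion_rate,
            rule,
        )

    controls = sim(0.0, replicates)

    def detected(values: np.ndarray) -> np.ndarray:
        u = rng.random(len(values))
        greater = (controls[None, :] > values[:, None]).sum(axis=1)
        equal = (controls[None, :] == values[:, None]).sum(axis=1)
        pvals = (greater + u * (equal + 1)) / (len(controls) + 1)
        return pvals <= alpha

    rows = []
    means = []
    for fraction in grid:
        est = sim(fraction, replicates)
        rows.append({"fraction": fraction, "detection_rate": float(detected(est).mean())})
        means.append(est.mean())

    null_est = sim(0.0, replicates)
    false_rate = float(detected(null_est).mean())
    slope = float(np.polyfit(grid, means, 1)[0]) if len(grid) > 1 else float("nan")
    rate_table = pd.DataFrame(rows)
    hits = rate_table[rate_table.detection_rate >= 0.95]
    limit = float(hits.fraction.iloc[0]) if len(hits) else float("nan")
    return DetectionLimitResult(
        limit, rate_table, false_rate, slope, alpha, reads_per_marker, replicates
    )
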