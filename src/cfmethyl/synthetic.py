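"""Synthetic bisulfite amplicon reads and a synthetic HCT cohort.

Two generators make the whole pipeline testable without any sequencing data:

* :func:`generate_reads` emulates the spike-in experiments used to establish
  assay sensitivity: genomic DNA of one or more target tissues mixed into a
  leukocyte background, amplified at the panel loci, bisulfite-converted and
  sequenced. A molecule drawn from cell type *c* is fully unmethylated at the
  loci targeting *c* and fully methylated everywhere else; the only departures
  from all-or-none methylation are the two per-CpG noise rates (incomplete
  conversion of unmethylated Cs, inappropriate conversion of methylated Cs).

* :func:`generate_cohort` emulates the case-control structure of an HCT
  cohort: three groups (healthy controls, transplanted without chronic GVHD,
  transplanted with chronic GVHD), log-normal biochemistry and cfDNA features
  sharing a latent "cell-death burden" factor, organ scores coupled to the
  matching organ's cfDNA, and completely-at-random feature missingness.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import CELLTYPES, SOLID_TISSUES, MarkerLocus, MarkerPanel

BACKGROUND = "leukocyte_other"

#: the 17 model features, in the canonical order used throughout the package
FEATURES_17 = (
    "ggtp",
    "alp",
    "alt",
    "ast",
    "tbil",
    "cfdna_total_ng_ml",
    "cf_skin",
    "cf_lung",
    "cf_gi",
    "cf_liver",
    "cf_neutrophil",
    "cf_monocyte",
    "cf_eosinophil",
    "cf_b_cell",
    "cf_t_cell",
    "cf_cd8_t",
    "cf_treg",
)

GROUPS = ("healthy", "hct_no_gvhd", "hct_cgvhd")


# -- reference sequences -----------------------------------------------------

def locus_reference(locus: MarkerLocus) -> str:
    """Deterministic synthetic reference sequence for one amplicon.

    Contains a CpG dinucleotide at every declared offset, no CpG anywhere
    else, and isolated (non-CpG) cytosines elsewhere so that bisulfite
    conversion efficiency can be assessed per molecule.
    """
    rng = np.random.default_rng(zlib.crc32(locus.marker_id.encode()))
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=locus.length, p=[0.3, 0.25, 0.15, 0.3])
    cpg = set(locus.cpg_offsets)
    for off in locus.cpg_offsets:
        seq[off] = "C"
        seq[off + 1] = "G"
    # destroy stray CpGs without touching the declared ones
    for i in range(locus.length - 1):
        if i in cpg:
            continue
        if seq[i] == "C" and seq[i + 1] == "G":
            if i + 1 in cpg:
                seq[i] = "T"
            else:
                seq[i + 1] = "A"
    return "".join(seq)


def noncpg_c_positions(locus: MarkerLocus, reference: str | None = None) -> np.ndarray:
    """Positions of cytosines outside the declared CpG sites."""
    ref = reference if reference is not None else locus_reference(locus)
    cpg = set(locus.cpg_offsets)
    return np.array([i for i, b in enumerate(ref) if b == "C" and i not in cpg], dtype=int)


# -- spike-in read simulation ------------------------------------------------

@dataclass
class MixtureSpec:
    """A tissue mixture to sequence at every panel locus.

    ``fractions`` maps cell types (panel targets, plus the ``leukocyte_other``
    background) to their share of the cfDNA pool. ``bisulfite_failure_rate``
    is the per-CpG probability that a truly unmethylated C escapes conversion
    (reads C); ``inappropriate_conversion_rate`` the probability a methylated
    C converts anyway (reads T).
    """

    fractions: dict[str, float]
    reads_per_marker: int = 10_000
    total_cfdna_ng_per_ml: float = 10.0
    bisulfite_failure_rate: float = 0.005
    inappropriate_conversion_rate: float = 0.005
    seed: int = 0

    def validate(self, panel: MarkerPanel) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")
        known = set(panel.celltypes) | {BACKGROUND}
        for ct in self.fractions:
            if ct not in known:
                raise ValueError(f"unknown cell type {ct!r}")
        for name in ("bisulfite_failure_rate", "inappropriate_conversion_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 0.1:
                raise ValueError(f"{name}={rate} outside [0, 0.1]")
        if self.reads_per_marker <= 0:
            raise ValueError("reads_per_marker must be positive")
        if self.total_cfdna_ng_per_ml <= 0:
            raise ValueError("total_cfdna_ng_per_ml must be positive")


def generate_reads(
    panel: MarkerPanel,
    spec: MixtureSpec,
    fastq_path: str | Path | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate bisulfite reads for ``spec`` at every locus of ``panel``.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_name, sequence)`` and ``truth`` records each molecule's source
    cell type and whether it was unmethylated at its locus. If ``fastq_path``
    is given the reads are additionally written as FASTQ (constant quality);
    output is byte-identical across runs with the same spec and seed.
    """
    spec.validate(panel)
    rng = np.random.default_rng(spec.seed)
    celltypes = sorted(spec.fractions)
    probs = np.array([spec.fractions[ct] for ct in celltypes])
    bf = spec.bisulfite_failure_rate
    ic = spec.inappropriate_conversion_rate

    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple[str, str, str, bool]] = []
    for locus in panel.loci:
        ref = locus_reference(locus)
        n = spec.reads_per_marker
        src = rng.choice(len(celltypes), size=n, p=probs)
        unmeth = np.array([celltypes[s] == locus.target_celltype for s in src])

        offs = np.array(locus.cpg_offsets)
        nonc = noncpg_c_positions(locus, ref)
        # converted template: every C reads T unless noise puts it back
        template = np.frombuffer(ref.encode(), dtype="S1").copy()
        template[offs] = b"T"
        template[nonc] = b"T"
        arr = np.tile(template, (n, 1))
        # CpG sites: methylated molecules read C (unless inappropriately
        # converted); unmethylated molecules read C only on conversion failure
        flip = rng.random((n, len(offs)))
        read_c = np.where(unmeth[:, None], flip < bf, flip >= ic)
        rows, cols = np.nonzero(read_c)
        arr[rows, offs[cols]] = b"C"
        # non-CpG Cs are genomically unmethylated: read C only on failure
        if len(nonc):
            fail = rng.random((n, len(nonc))) < bf
            rows, cols = np.nonzero(fail)
            arr[rows, nonc[cols]] = b"C"

        for i in range(n):
            name = f"{locus.marker_id}:{i:06d}"
            reads.append((name, arr[i].tobytes().decode()))
            truth_rows.append((locus.marker_id, name, celltypes[src[i]], bool(unmeth[i])))

    truth = pd.DataFrame(
        truth_rows, columns=["marker_id", "molecule_id", "source_celltype", "unmethylated"]
    )
    if fastq_path is not None:
        with open(fastq_path, "w", encoding="utf-8") as fh:
            for name, seq in reads:
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return reads, truth


# -- cohort simulation -------------------------------------------------------

#: healthy-group median of each feature (IU/L for enzymes, mg/dL for TBil,
#: ng/mL for total cfDNA, genome equivalents/mL for cell-type cfDNA)
BASELINE_MEDIANS: dict[str, float] = {
    "ggtp": 25.0,
    "alp": 80.0,
    "alt": 20.0,
    "ast": 25.0,
    "tbil": 0.6,
    "cfdna_total_ng_ml": 5.0,
    "cf_skin": 15.0,
    "cf_lung": 10.0,
    "cf_gi": 20.0,
    "cf_liver": 30.0,
    "cf_neutrophil": 300.0,
    "cf_monocyte": 50.0,
    "cf_eosinophil": 20.0,
    "cf_b_cell": 30.0,
    "cf_t_cell": 50.0,
    "cf_cd8_t": 20.0,
    "cf_treg": 5.0,
}

#: log-scale elevation in both HCT groups relative to healthy controls
#: (tissue turnover persists after transplant even without overt disease)
DEFAULT_HCT_SHIFT: dict[str, float] = {
    "cf_gi": 0.4,
    "cf_liver": 0.4,
    "cf_lung": 0.4,
    "cf_t_cell": 0.4,
    "cf_cd8_t": 0.4,
    "cf_neutrophil": 0.3,
}

#: log-scale elevation of the chronic-GVHD group. These are the planted
#: signal features; magnitudes are calibrated so the 3-feature classifier
#: reaches a cross-validated AUC near 0.8 on the default cohort.
DEFAULT_EFFECTS: dict[str, float] = {
    "alt": 0.8,
    "cfdna_total_ng_ml": 0.8,
    "cf_monocyte": 0.8,
}

_ORGAN_FEATURE = {"skin": "cf_skin", "gi": "cf_gi", "liver": "cf_liver", "lung": "cf_lung"}


@dataclass
class CohortSpec:
    """Parameters of the synthetic HCT cohort.

    Group sizes default to the study design (36 transplanted without chronic
    GVHD, 65 with; healthy-control count is a stand-in). ``missing_rate``
    defaults to 8/101 so the expected complete-case count among the 101 HCT
    samples is 93. ``latent_loading`` scales a shared per-sample factor that
    induces positive correlation among all features; ``organ_score_delta`` is
    the extra log-shift of an organ's cfDNA per unit of its NIH score (0-3).
    """

    n_healthy: int = 25
    n_hct_no_gvhd: int = 36
    n_hct_cgvhd: int = 65
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    hct_shift: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HCT_SHIFT))
    latent_loading: float = 0.3
    sigma: float = 0.6
    organ_score_delta: float = 0.15
    missing_rate: float = 8 / 101
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_healthy, self.n_hct_no_gvhd, self.n_hct_cgvhd) < 0:
            raise ValueError("group sizes must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for feat in list(self.effects) + list(self.hct_shift):
            if feat not in FEATURES_17:
                raise ValueError(f"unknown feature {feat!r}")


_SEVERITY = {0: "none", 1: "mild", 2: "moderate", 3: "severe"}


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Simulate a cohort table with one row per plasma sample.

    Features are log-normal around group-specific medians; the chronic-GVHD
    group is shifted up by ``spec.effects``, organ scores add
    ``organ_score_delta`` per point to the matching organ's cfDNA, and a
    shared standard-normal latent factor (scaled by ``latent_loading``)
    correlates all features within a sample. Missingness is injected
    completely at random via :func:`inject_missingness`.
    """
    spec = CohortSpec() if spec is None else spec
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_feat, rng_clin, rng_miss = (np.random.default_rng(s) for s in ss.spawn(3))

    groups = (
        ["healthy"] * spec.n_healthy
        + ["hct_no_gvhd"] * spec.n_hct_no_gvhd
        + ["hct_cgvhd"] * spec.n_hct_cgvhd
    )
    n = len(groups)
    rows: list[dict] = []
    for i, group in enumerate(groups):
        rec: dict = {"sample_id": f"S{i + 1:03d}", "group": group}
        # NIH organ scores: clinically evident disease means >=1 organ scored
        scores = {t: 0 for t in SOLID_TISSUES}
        if group == "hct_cgvhd":
            for t in SOLID_TISSUES:
                scores[t] = int(rng_clin.choice(4, p=[0.45, 0.25, 0.2, 0.1]))
            if max(scores.values()) == 0:
                scores[str(rng_clin.choice(SOLID_TISSUES))] = 1
        for t in SOLID_TISSUES:
            rec[f"score_{t}"] = scores[t]
        rec["severity"] = _SEVERITY[max(scores.values())]
        if group == "healthy":
            rec["days_post_hct"] = np.nan
        else:
            rec["days_post_hct"] = int(101 + rng_clin.lognormal(mean=np.log(680.0), sigma=1.1))

        latent = rng_feat.standard_normal()
        for feat in FEATURES_17:
            mu = np.log(BASELINE_MEDIANS[feat])
            if group != "healthy":
                mu += spec.hct_shift.get(feat, 0.0)
            if group == "hct_cgvhd":
                mu += spec.effects.get(feat, 0.0)
            for organ, organ_feat in _ORGAN_FEATURE.items():
                if feat == organ_feat:
                    mu += spec.organ_score_delta * scores[organ]
            rec[feat] = float(
                np.exp(mu + spec.latent_loading * latent + spec.sigma * rng_feat.standard_normal())
            )
        rows.append(rec)

    table = pd.DataFrame(rows)
    if spec.missing_rate > 0:
        table = inject_missingness(
            table, spec.missing_rate, seed=int(rng_miss.integers(2**31))
        )
    return table


def inject_missingness(
    table: pd.DataFrame,
    rate: float,
    seed: int = 0,
    columns: tuple[str, ...] = FEATURES_17,
) -> pd.DataFrame:
    """Blank >=1 feature in a random ``rate`` fraction of samples (MCAR).

    Returns a copy; the input table is untouched. A flagged sample loses
    between one and three of ``columns``, chosen uniformly.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = table.copy()
    flagged = rng.random(len(out)) < rate
    for idx in np.nonzero(flagged)[0]:
        k = int(rng.integers(1, 4))
        for col in rng.choice(columns, size=min(k, len(columns)), replace=False):
            out.iloc[idx, out.columns.get_loc(col)] = np.nan
    return out
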