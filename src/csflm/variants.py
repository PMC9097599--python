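"""Somatic variant filtering and paired CSF-vs-plasma comparison.

Targeted-sequencing calls from the two liquid-biopsy compartments are
filtered by allele fraction, unique-read support and germline status,
restricted to the gene panel shared by the capture designs, and partitioned
into shared / CSF-only / plasma-only alterations. Matching is by exact
nucleotide change: the same protein change arising from different
nucleotide substitutions (e.g. EGFR C797S via 2390G>C vs 2389T>A) is
evidence of independent evolution in the two compartments and is *not*
counted as shared.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

VARIANT_CLASSES = ("SNV", "indel", "CNV", "fusion")
DEFAULT_MIN_VAF = 0.001  # "allele fraction below 0.1%" is disregarded
DEFAULT_MIN_READS = 4
LOH_VAF_THRESHOLD = 0.5


@dataclass(frozen=True)
class VariantCall:
    """One alteration in one sample.

    ``nt_change`` is the nucleotide-level description (e.g. "2390G>C"); for
    CNVs ``cnv_direction`` ("gain"/"loss") takes its place in the identity
    key; for fusions ``nt_change`` carries the gene pair (e.g. "EML4-ALK").
    """

    sample_id: str
    gene: str
    var_class: str
    vaf: float
    unique_reads: int
    germline_flag: bool = False
    chrom: str | None = None
    pos: int | None = None  # 1-based
    ref: str | None = None
    alt: str | None = None
    protein_change: str | None = None
    nt_change: str | None = None
    cnv_direction: str | None = None

    def __post_init__(self) -> None:
        if self.var_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.var_class!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.unique_reads < 0:
            raise ValueError("unique_reads must be >= 0")
        if self.var_class in ("SNV", "indel") and (
            self.chrom is None or self.pos is None
        ):
            raise ValueError(f"{self.var_class} call requires coordinates")
        if self.var_class == "CNV" and self.cnv_direction not in ("gain", "loss"):
            raise ValueError("CNV call requires cnv_direction gain/loss")

    @property
    def key(self) -> tuple[str, str]:
        """Identity used for cross-compartment matching."""
        if self.var_class == "CNV":
            return (self.gene, f"cnv:{self.cnv_direction}")
        return (self.gene, self.nt_change or "")


@dataclass
class SampleVariantSet:
    """Filtered alterations of one compartment of one patient."""

    compartment: str  # "CSF" | "plasma"
    patient_id: str
    calls: dict[tuple[str, str], VariantCall] = field(default_factory=dict)

    @classmethod
    def from_calls(
        cls, compartment: str, patient_id: str, calls: list[VariantCall]
    ) -> "SampleVariantSet":
        keyed: dict[tuple[str, str], VariantCall] = {}
        for call in calls:
            if call.key in keyed:
                raise ValueError(f"duplicate variant key {call.key}")
            keyed[call.key] = call
        return cls(compartment, patient_id, keyed)

    def __len__(self) -> int:
        return len(self.calls)


@dataclass
class ComparisonResult:
    patient_id: str
    shared: list[VariantCall]
    csf_only: list[VariantCall]
    plasma_only: list[VariantCall]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.shared), len(self.csf_only), len(self.plasma_only))

    def to_dict(self) -> dict:
        shared, csf_only, plasma_only = self.counts
        return {
            "patient_id": self.patient_id,
            "shared": shared,
            "csf_only": csf_only,
            "plasma_only": plasma_only,
            "total": shared + csf_only + plasma_only,
        }


# ---------------------------------------------------------------------------
# filters and comparisons
# ---------------------------------------------------------------------------

def filter_calls(
    calls: list[VariantCall],
    min_vaf: float = DEFAULT_MIN_VAF,
    min_reads: int = DEFAULT_MIN_READS,
) -> list[VariantCall]:
    """Drop unreliable and germline calls.

    A call survives when its allele fraction is at least ``min_vaf``
    (default 0.1%), it is supported by at least ``min_reads`` unique reads
    (default 4) and it is not flagged germline.
    """
    return [
        c
        for c in calls
        if c.vaf >= min_vaf and c.unique_reads >= min_reads and not c.germline_flag
    ]


def restrict_to_panel(
    calls: list[VariantCall], panel: set[str]
) -> list[VariantCall]:
    """Keep calls in genes covered by every capture panel used."""
    if not panel:
        raise ValueError("gene panel is empty")
    return [c for c in calls if c.gene in panel]


def load_panel(path=None) -> set[str]:
    """Load a one-gene-per-line panel file.

    Without ``path``, returns the packaged 84-gene lung-cancer panel. That
    list is a stand-in for the capture vendors' shared design (which is not
    public) and is meant to be replaced with the user's own panel file.
    """
    if path is None:
        text = (
            resources.files("csflm").joinpath("data/panel_genes.txt").read_text()
        )
    else:
        with open(path) as handle:
            text = handle.read()
    genes = {
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }
    if not genes:
        raise ValueError("gene panel is empty")
    return genes


def partition_alterations(
    csf: SampleVariantSet, plasma: SampleVariantSet
) -> ComparisonResult:
    """Split a patient's alterations into shared / CSF-only / plasma-only.

    Inputs must already be filtered and panel-restricted. Small variants
    match on (gene, exact nucleotide change); CNVs on (gene, direction).
    """
    if csf.patient_id != plasma.patient_id:
        raise ValueError(
            f"patient mismatch: {csf.patient_id!r} vs {plasma.patient_id!r}"
        )
    csf_keys = set(csf.calls)
    plasma_keys = set(plasma.calls)
    shared = [csf.calls[k] for k in sorted(csf_keys & plasma_keys)]
    csf_only = [csf.calls[k] for k in sorted(csf_keys - plasma_keys)]
    plasma_only = [plasma.calls[k] for k in sorted(plasma_keys - csf_keys)]
    return ComparisonResult(csf.patient_id, shared, csf_only, plasma_only)


_DRIVER_RE = re.compile(r"^(?P<gene>[A-Za-z0-9]+)\.(?P<variant>\S+)$")


def parse_driver(driver: str) -> tuple[str, str, str]:
    """Parse a clinical driver string into (gene, variant, kind).

    Accepts "GENE.variant" (e.g. "EGFR.L858R", "ERBB2.G776delinsVV") and
    "A-B fusion" (e.g. "EML4-ALK fusion").
    """
    driver = driver.strip()
    if driver.lower().endswith("fusion"):
        pair = driver[: -len("fusion")].strip()
        if "-" not in pair:
            raise ValueError(f"cannot parse fusion driver {driver!r}")
        return pair, pair, "fusion"
    match = _DRIVER_RE.match(driver)
    if not match:
        raise ValueError(f"cannot parse driver string {driver!r}")
    return match["gene"], match["variant"], "small"


def detect_driver(
    variant_set: SampleVariantSet, driver: str
) -> tuple[bool, float | None]:
    """Was the primary tumor's driver alteration seen in this compartment?

    Small variants match on gene + protein change; fusions match on the
    gene pair (either partner's symbol, or the pair recorded on the call).
    Returns (detected, VAF of the matching call or None).
    """
    gene, variant, kind = parse_driver(driver)
    for call in variant_set.calls.values():
        if kind == "fusion":
            partners = set(gene.split("-"))
            recorded = call.nt_change or call.protein_change or ""
            if call.var_class == "fusion" and (
                call.gene in partners or recorded == gene
            ):
                return True, call.vaf
        else:
            if call.gene == gene and call.protein_change == variant:
                return True, call.vaf
    return False, None


def flag_loh(vaf: float, threshold: float = LOH_VAF_THRESHOLD) -> bool:
    """Somatic VAF strictly above 50% suggests loss of heterozygosity."""
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"VAF {vaf} outside [0, 1]")
    return vaf > threshold


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "sample_id", "gene", "var_class", "chrom", "pos", "ref", "alt",
    "protein_change", "nt_change", "cnv_direction", "vaf", "unique_reads",
    "germline_flag",
]


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(c, col) for col in _TSV_COLUMNS] for c in calls],
        columns=_TSV_COLUMNS,
    )


def write_calls_tsv(calls: list[VariantCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[VariantCall]:
    table = pd.read_csv(path, sep="\t")
    missing = {"gene", "var_class", "vaf", "unique_reads"} - set(table.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    calls = []
    for row in table.to_dict("records"):
        def clean(value):
            return None if pd.isna(value) else value

        calls.append(
            VariantCall(
                sample_id=str(clean(row.get("sample_id")) or ""),
                gene=str(row["gene"]),
                var_class=str(row["var_class"]),
                vaf=float(row["vaf"]),
                unique_reads=int(row["unique_reads"]),
                germline_flag=bool(row.get("germline_flag", False)),
                chrom=clean(row.get("chrom")),
                pos=int(row["pos"]) if clean(row.get("pos")) is not None else None,
                ref=clean(row.get("ref")),
                alt=clean(row.get("alt")),
                protein_change=clean(row.get("protein_change")),
                nt_change=clean(row.get("nt_change")),
                cnv_direction=clean(row.get("cnv_direction")),
            )
        )
    return calls


def read_calls_vcf(path, sample_id: str = "") -> list[VariantCall]:
    """Read small variants from a VCF.

    VAF comes from FORMAT/AF when present, else alt/total of FORMAT/AD;
    unique-read support from the alt depth of FORMAT/AD. Gene and protein
    change are taken from INFO/GENE and INFO/PCHANGE when present.
    """
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            if not record.alts:
                continue
            alt = record.alts[0]
            sample = record.samples[0] if record.samples else None
            vaf, alt_reads = 0.0, 0
            if sample is not None:
                ad = sample.get("AD")
                if ad is not None and len(ad) >= 2 and ad[0] is not None:
                    alt_reads = int(ad[1])
                    total = sum(int(x) for x in ad if x is not None)
                    vaf = alt_reads / total if total else 0.0
                af = sample.get("AF")
                if af is not None:
                    vaf = float(af[0] if isinstance(af, tuple) else af)
            def info_get(key, default=None):
                try:
                    return record.info.get(key, default)
                except (KeyError, ValueError):  # key absent from header
                    return default

            gene = str(info_get("GENE", ""))
            is_indel = len(record.ref) != len(alt)
            calls.append(
                VariantCall(
                    sample_id=sample_id,
                    gene=gene,
                    var_class="indel" if is_indel else "SNV",
                    vaf=vaf,
                    unique_reads=alt_reads,
                    germline_flag=bool(info_get("GERMLINE", False)),
                    chrom=record.chrom,
                    pos=record.pos,
                    ref=record.ref,
                    alt=alt,
                    protein_change=str(info_get("PCHANGE", "")) or None,
                    nt_change=f"{record.pos}{record.ref}>{alt}",
                )
            )
    return calls
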