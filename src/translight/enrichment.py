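"""RBP binding-site annotation and 3'UTR density enrichment.

Given eCLIP-style binding-site intervals (BED6; the name column carries the
RBP) and a gene model (GTF with explicit UTR/CDS features), each site is
assigned to the transcript region it mostly overlaps — 5'UTR, CDS, 3'UTR or
intron, else intergenic.  For a regulated ("DE") gene set, each RBP's 3'UTR
binding-site density (sites per kb) is compared with its density over the
whole annotated transcriptome; enrichment p-values come from a one-sided
binomial test against the length-proportional null and are BH-corrected
across RBPs.  Helpers scan 3'UTR sequences for AU-rich (AUUUA) and
pyrimidine-rich elements and compute UpSet-style exclusive intersection
counts over motif/category gene sets.

Coordinates are 0-based half-open internally; GTF (1-based closed) is
converted on read, BED is consumed natively.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "BindingSite",
    "RegionIndex",
    "REGION_PRIORITY",
    "read_gtf_models",
    "read_bed_sites",
    "assign_region",
    "rbps_bound_to_genes",
    "density_enrichment",
    "scan_au_rich",
    "scan_pyrimidine_rich",
    "intersection_counts",
    "load_rbp_categories",
    "categorize_rbps",
]

REGIONS = ("five_prime_utr", "cds", "three_prime_utr", "intron")
#: Tie-break priority after maximal overlap (regulatory regions favored).
REGION_PRIORITY = {"three_prime_utr": 0, "five_prime_utr": 1, "cds": 2, "intron": 3}
CATEGORIES = ("stress_granule", "p_body", "m6a_reader", "splicing")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"malformed interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """One canonical transcript per gene with explicit region intervals."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def region_length(self, region: str) -> int:
        return sum(e - s for s, e in self.regions.get(region, []))

    @property
    def utr3_kb(self) -> float:
        return self.region_length("three_prime_utr") / 1000.0


@dataclass(frozen=True)
class BindingSite:
    rbp: str
    interval: GenomicInterval
    source_cell_line: str = ""
    score: float = 0.0


def read_gtf_models(path: str) -> dict[str, GeneModel]:
    """Load gene models from GTF, one canonical transcript per gene.

    Expects gene/transcript/exon/CDS/five_prime_utr/three_prime_utr
    features.  Introns are derived as the transcript span minus exons.
    Among multiple transcripts of a gene the one with the longest 3'UTR
    is kept.
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", keep_order=True, merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    models: dict[str, GeneModel] = {}
    for tx in db.features_of_type("transcript"):
        gene_id = tx.attributes.get("gene_id", [tx.id])[0]
        model = GeneModel(
            gene_id=gene_id,
            transcript_id=tx.attributes.get("transcript_id", [tx.id])[0],
            chrom=tx.seqid,
            strand=tx.strand,
        )
        exons: list[tuple[int, int]] = []
        for child in db.children(tx, order_by="start"):
            iv = (child.start - 1, child.end)  # GTF 1-based closed -> half-open
            ftype = child.featuretype.lower()
            if ftype == "exon":
                exons.append(iv)
            elif ftype == "cds":
                model.regions.setdefault("cds", []).append(iv)
            elif ftype in ("five_prime_utr", "three_prime_utr"):
                model.regions.setdefault(ftype, []).append(iv)
        exons.sort()
        introns = [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]
        ]
        if introns:
            model.regions["intron"] = introns
        prev = models.get(gene_id)
        if prev is None or model.region_length("three_prime_utr") > prev.region_length(
            "three_prime_utr"
        ):
            models[gene_id] = model
    return models


def read_bed_sites(path: str) -> list[BindingSite]:
    """Read BED6 binding sites; the name column is the RBP identifier."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return [
        BindingSite(
            rbp=str(r.name),
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end), str(r.strand)),
            score=float(r.score),
        )
        for r in df.itertuples(index=False)
    ]


class RegionIndex:
    """Interval index over all gene-model regions for fast site assignment."""

    def __init__(self, models: Mapping[str, GeneModel]):
        self.models = dict(models)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for gm in self.models.values():
            tree = self._trees.setdefault((gm.chrom, gm.strand), IntervalTree())
            for region, ivs in gm.regions.items():
                for s, e in ivs:
                    tree[s:e] = (gm.gene_id, region)

    def assign(self, site: BindingSite) -> tuple[str, str | None]:
        """Region label and gene for one site.

        The site goes to the (gene, region) with maximal overlap length;
        ties break by 3'UTR > 5'UTR > CDS > intron, then gene id.  Sites
        overlapping nothing on the matching strand are intergenic.
        """
        iv = site.interval
        tree = self._trees.get((iv.chrom, iv.strand))
        if tree is None:
            return "intergenic", None
        overlaps: dict[tuple[str, str], int] = {}
        for hit in tree.overlap(iv.start, iv.end):
            ov = min(iv.end, hit.end) - max(iv.start, hit.begin)
            if ov > 0:
                overlaps[hit.data] = overlaps.get(hit.data, 0) + ov
        if not overlaps:
            return "intergenic", None
        (gene_id, region), _ = min(
            overlaps.items(),
            key=lambda kv: (-kv[1], REGION_PRIORITY[kv[0][1]], kv[0][0]),
        )
        return region, gene_id


def assign_region(
    site: BindingSite, models: Mapping[str, GeneModel] | RegionIndex
) -> tuple[str, str | None]:
    """Convenience wrapper; build a RegionIndex for repeated assignment."""
    index = models if isinstance(models, RegionIndex) else RegionIndex(models)
    return index.assign(site)


def rbps_bound_to_genes(
    sites: Sequence[BindingSite],
    genes: Sequence[str],
    models: Mapping[str, GeneModel] | RegionIndex,
) -> tuple[dict[str, set[str]], int]:
    """RBPs bound anywhere in each listed gene (non-intergenic regions only).

    Returns the per-gene RBP sets and the distinct-RBP count across genes.
    Unknown gene ids are skipped with a warning.
    """
    import warnings

    index = models if isinstance(models, RegionIndex) else RegionIndex(models)
    known = [g for g in genes if g in index.models]
    for g in genes:
        if g not in index.models:
            warnings.warn(f"unknown gene id skipped: {g}")
    wanted = set(known)
    bound: dict[str, set[str]] = {g: set() for g in known}
    for site in sites:
        region, gene = index.assign(site)
        if gene in wanted and region != "intergenic":
            bound[gene].add(site.rbp)
    distinct = len(set().union(*bound.values())) if bound else 0
    return bound, distinct


def density_enrichment(
    sites: Sequence[BindingSite],
    de_genes: Sequence[str],
    models: Mapping[str, GeneModel] | RegionIndex,
    region: str = "three_prime_utr",
    exclude_de_from_background: bool = False,
) -> pd.DataFrame:
    """Per-RBP binding-site density enrichment in DE-gene regions.

    density_de = sites in DE-gene `region` / kb of DE `region`; density_bg
    is the same over all annotated genes (DE genes included in the
    background unless excluded).  fold = density_de / density_bg.  The
    p-value is a one-sided binomial test of the DE site count among all of
    the RBP's region sites against the length proportion kb_de / kb_bg,
    BH-corrected across RBPs.
    """
    if len(de_genes) == 0:
        raise ValueError("de_genes must be non-empty")
    index = models if isinstance(models, RegionIndex) else RegionIndex(models)
    de_set = set(de_genes)
    unknown = de_set - set(index.models)
    if unknown:
        raise KeyError(f"unknown DE genes: {sorted(unknown)}")

    bg_models = {
        g: m for g, m in index.models.items()
        if not (exclude_de_from_background and g in de_set)
    }
    kb_de = sum(index.models[g].region_length(region) for g in de_set) / 1000.0
    kb_bg = sum(m.region_length(region) for m in bg_models.values()) / 1000.0
    if kb_bg <= 0 or kb_de <= 0:
        raise ValueError(f"region {region} has zero annotated length")

    counts_de: dict[str, int] = {}
    counts_bg: dict[str, int] = {}
    for site in sites:
        reg, gene = index.assign(site)
        if reg != region or gene is None:
            continue
        if gene in bg_models:
            counts_bg[site.rbp] = counts_bg.get(site.rbp, 0) + 1
        if gene in de_set:
            counts_de[site.rbp] = counts_de.get(site.rbp, 0) + 1

    rows = []
    p_null = kb_de / kb_bg if not exclude_de_from_background else kb_de / (kb_bg + kb_de)
    for rbp in sorted(set(counts_bg) | set(counts_de)):
        n_de = counts_de.get(rbp, 0)
        n_bg = counts_bg.get(rbp, 0)
        d_de = n_de / kb_de
        d_bg = n_bg / kb_bg
        fold = d_de / d_bg if d_bg > 0 else np.inf if d_de > 0 else 0.0
        if n_de == 0:
            p = 1.0
        else:
            trials = n_bg if not exclude_de_from_background else n_bg + n_de
            p = float(stats.binomtest(n_de, trials, p_null, alternative="greater").pvalue)
        rows.append(
            dict(rbp=rbp, n_sites_de=n_de, kb_de=kb_de, n_sites_bg=n_bg,
                 kb_bg=kb_bg, density_de=d_de, density_bg=d_bg, fold=fold, p=p)
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = []
    return out


_RNA_OK = set("ACGUT")


def _to_rna(seq: str) -> str:
    seq = seq.upper()
    if not set(seq) <= _RNA_OK:
        raise ValueError("sequence contains non-ACGU/T characters")
    return seq.replace("T", "U")


def scan_au_rich(seq: str, min_count: int = 1) -> tuple[int, bool]:
    """Count possibly-overlapping AUUUA pentamers (T treated as U)."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    s = _to_rna(seq)
    count = 0
    pos = s.find("AUUUA")
    while pos != -1:
        count += 1
        pos = s.find("AUUUA", pos + 1)
    return count, count >= min_count


def scan_pyrimidine_rich(
    seq: str, window: int = 20, min_frac: float = 0.8
) -> tuple[float, bool]:
    """Maximum pyrimidine (C/U) fraction over sliding windows."""
    s = _to_rna(seq)
    if len(s) < window:
        raise ValueError(f"sequence shorter than window ({len(s)} < {window})")
    is_pyr = np.frombuffer(s.encode(), dtype=np.uint8)
    is_pyr = ((is_pyr == ord("C")) | (is_pyr == ord("U"))).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(is_pyr)])
    frac = (csum[window:] - csum[:-window]) / window
    max_frac = float(frac.max())
    return max_frac, max_frac >= min_frac


def intersection_counts(
    named_sets: Mapping[str, set], universe: set
) -> dict[frozenset, int]:
    """Exclusive (UpSet-style) intersection counts over a finite universe.

    Each universe element is counted once, under the exact combination of
    set names containing it; the empty frozenset key holds the remainder.
    Counts always sum to |universe|.
    """
    for name, s in named_sets.items():
        extra = set(s) - universe
        if extra:
            raise ValueError(f"set {name!r} has elements outside the universe: {sorted(extra)[:5]}")
    counts: dict[frozenset, int] = {}
    for el in universe:
        key = frozenset(name for name, s in named_sets.items() if el in s)
        counts[key] = counts.get(key, 0) + 1
    return counts


def load_rbp_categories(path: str | None = None) -> dict[str, set[str]]:
    """RBP -> functional category set from a static configuration table.

    The packaged default covers stress-granule, P-body, m6A-reader and
    splicing assignments for the RBPs most relevant to granule-mediated
    translational control.
    """
    if path is None:
        ref = importlib.resources.files("translight") / "data" / "rbp_categories.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    table: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        cats = {c.strip() for c in str(r.categories).split(",") if c.strip()}
        bad = cats - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories for {r.rbp}: {sorted(bad)}")
        table[str(r.rbp)] = cats
    return table


def categorize_rbps(
    rbps: Sequence[str], table: Mapping[str, set[str]] | None = None
) -> pd.DataFrame:
    """Category membership counts for a list of RBPs.

    Returns one row per RBP with boolean category columns; RBPs absent
    from the table get the `uncategorized` flag.
    """
    if table is None:
        table = load_rbp_categories()
    rows = []
    for rbp in rbps:
        cats = table.get(rbp)
        rows.append(
            {"rbp": rbp, "uncategorized": cats is None}
            | {c: bool(cats and c in cats) for c in CATEGORIES}
        )
    return pd.DataFrame(rows, columns=["rbp", *CATEGORIES, "uncategorized"])
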