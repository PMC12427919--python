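"""Synthetic-data generators with machine-readable ground truth.

Every pipeline stage has a generator here that produces inputs with the
statistical structure the corresponding analysis assumes, plus a truth
table enumerating the generated entities and which of them carry a planted
effect.  All generators are pure functions of their parameters and seed
(re-running is byte-identical), and a single global seed can be split into
independent per-generator substreams with :func:`substream_seed`.

Truth tables are DataFrames with columns ``entity_id``, ``entity_kind``,
``is_positive``, ``effect_size`` and ``params`` (semicolon-joined
``name=value`` pairs); positives always have nonzero effect size.
"""

from __future__ import annotations

import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import BindingSite, GeneModel, GenomicInterval
from .signature import CodonPair, TranscriptRecord

__all__ = [
    "substream_seed",
    "truth_frame",
    "synth_transcriptome",
    "synth_plate",
    "synth_gene_models",
    "synth_eclip",
    "synth_cetsa",
    "synth_ribo",
    "synth_dose_panel",
    "synth_control_cells",
    "synth_fret_plate",
]

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


def substream_seed(seed: int, label: str) -> int:
    """Derive a deterministic per-stage seed from one global seed."""
    return int(np.random.SeedSequence([seed, zlib.crc32(label.encode())]).generate_state(1)[0] % (2**31))


def _params_str(params: Mapping[str, float]) -> str:
    return ";".join(f"{k}={v:g}" for k, v in params.items())


def truth_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble a truth table; every entity appears exactly once."""
    df = pd.DataFrame(
        rows, columns=["entity_id", "entity_kind", "is_positive", "effect_size", "params"]
    )
    if df["entity_id"].duplicated().any():
        raise ValueError("duplicate entity in truth table")
    if ((df["effect_size"] == 0) != ~df["is_positive"]).any():
        raise ValueError("truth invariant violated: effect_size == 0 <=> not positive")
    return df


# ---------------------------------------------------------------------------
# Transcriptome with a planted rare codon pair
# ---------------------------------------------------------------------------

def synth_transcriptome(
    n_transcripts: int,
    codon_length_range: tuple[int, int] = (100, 600),
    planted_pair: CodonPair = CodonPair("TCG", "CAA"),
    planted_prevalence: int = 5,
    target_boost: float = 8.0,
    seed: int = 0,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Random CDS set where exactly `planted_prevalence` transcripts carry the pair.

    The first pair-containing transcript is the designated target and gets
    abundance and ribosome density boosted by ``target_boost`` so that it
    dominates the occupancy over the planted pair, emulating the
    prevalence structure a signature pair needs (rare pair, one transcript
    carrying most of the traffic).  All other transcripts are scrubbed of
    accidental occurrences of the pair.
    """
    if not (n_transcripts >= planted_prevalence >= 1):
        raise ValueError("need n_transcripts >= planted_prevalence >= 1")
    if codon_length_range[0] < 2:
        raise ValueError("transcripts need at least 2 codons")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(codon_length_range[0], codon_length_range[1] + 1, n_transcripts)
    planted_idx = set(rng.choice(n_transcripts, planted_prevalence, replace=False).tolist())
    target_idx = min(planted_idx)

    records: list[TranscriptRecord] = []
    truth_rows: list[dict] = []
    pair = (planted_pair.first, planted_pair.second)
    for i in range(n_transcripts):
        n_cod = int(lengths[i])
        codons = [_CODONS[j] for j in rng.integers(0, 64, n_cod)]
        # scrub accidental occurrences, then plant where required
        changed = True
        while changed:
            changed = False
            for j in range(n_cod - 1):
                if (codons[j], codons[j + 1]) == pair:
                    codons[j + 1] = _CODONS[int(rng.integers(0, 64))]
                    changed = True
        if i in planted_idx:
            j = int(rng.integers(0, n_cod - 1))
            codons[j], codons[j + 1] = pair
        abundance = float(rng.lognormal(np.log(10.0), 1.0))
        density = float(rng.lognormal(0.0, 0.3))
        if i == target_idx:
            abundance *= target_boost
            density *= 1.5
        tid = f"TX{i:05d}"
        records.append(TranscriptRecord(tid, "".join(codons), abundance, density))
        is_pos = i in planted_idx
        truth_rows.append(
            dict(
                entity_id=tid, entity_kind="transcript", is_positive=is_pos,
                effect_size=(target_boost if i == target_idx else 1.0) if is_pos else 0.0,
                params=_params_str(
                    {"is_target": float(i == target_idx), "abundance": abundance,
                     "ribo_density": density}
                ),
            )
        )
    return records, truth_frame(truth_rows)


# ---------------------------------------------------------------------------
# Imaging plate with correlated well features
# ---------------------------------------------------------------------------

def _check_correlation(r: np.ndarray, k: int) -> np.ndarray:
    r = np.asarray(r, float)
    if r.shape != (k, k) or not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
        raise ValueError("feature_correlation must be symmetric with unit diagonal")
    try:
        np.linalg.cholesky(r)
    except np.linalg.LinAlgError as exc:
        raise ValueError("feature_correlation must be positive-definite") from exc
    return r


def synth_plate(
    n_null_wells: int,
    n_active_wells: int,
    n_features: int = 10,
    feature_correlation: np.ndarray | None = None,
    active_shift: np.ndarray | None = None,
    cells_per_well: int = 200,
    cell_sigma: float = 1.0,
    well_sigma: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell feature table for a screening plate with spiked actives.

    Cell feature vectors follow ``mu + b_w + e_c`` with well effects
    ``b_w ~ N(0, well_sigma^2 R)`` and cell noise ``N(0, cell_sigma^2 R)``.
    ``active_shift`` is expressed in SD units of the *well-level median
    profile* under the null (SD = sqrt(well_sigma^2 +
    cell_sigma^2 * (pi/2) / n_cells)), so a 6-SD spike means a well whose
    median profile sits six null SDs from the reference — the scale on
    which screen scores are computed.
    """
    k = n_features
    r = np.eye(k) if feature_correlation is None else _check_correlation(feature_correlation, k)
    shift = np.zeros(k) if active_shift is None else np.asarray(active_shift, float)
    if shift.shape != (k,):
        raise ValueError("active_shift length must equal n_features")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(r)
    well_sd = np.sqrt(well_sigma**2 + cell_sigma**2 * (np.pi / 2) / cells_per_well)

    frames, truth_rows = [], []
    n_total = n_null_wells + n_active_wells
    for w in range(n_total):
        active = w >= n_null_wells
        well_id = f"W{w:05d}"
        n_cells = max(2, int(rng.poisson(cells_per_well)))
        b = well_sigma * (chol @ rng.standard_normal(k))
        delta = shift * well_sd if active else np.zeros(k)
        cells = (
            b + delta
            + cell_sigma * (rng.standard_normal((n_cells, k)) @ chol.T)
        )
        df = pd.DataFrame(cells, columns=[f"feature_{i}" for i in range(k)])
        df.insert(0, "cell_id", [f"{well_id}:C{i:04d}" for i in range(n_cells)])
        df.insert(0, "well_id", well_id)
        df["role"] = "compound" if active else "dmso"
        frames.append(df)
        effect = float(np.linalg.norm(delta / well_sd)) if active else 0.0
        truth_rows.append(
            dict(entity_id=well_id, entity_kind="well",
                 is_positive=bool(active and effect > 0), effect_size=effect,
                 params=_params_str({"n_cells": n_cells}))
        )
    return pd.concat(frames, ignore_index=True), truth_frame(truth_rows)


# ---------------------------------------------------------------------------
# Gene models and eCLIP sites
# ---------------------------------------------------------------------------

def synth_gene_models(
    n_genes: int,
    seed: int = 0,
    chrom: str = "chrS",
    utr5_range: tuple[int, int] = (100, 300),
    cds_range: tuple[int, int] = (300, 1500),
    utr3_range: tuple[int, int] = (500, 3500),
    intron_range: tuple[int, int] = (200, 2000),
    max_introns: int = 2,
    gap: int = 1000,
) -> dict[str, GeneModel]:
    """Single-chromosome gene models with UTRs, CDS and CDS-internal introns."""
    rng = np.random.default_rng(seed)
    models: dict[str, GeneModel] = {}
    pos = gap
    for g in range(n_genes):
        gene_id = f"G{g:05d}"
        strand = "+" if g % 2 == 0 else "-"
        utr5 = int(rng.integers(*utr5_range))
        cds = int(rng.integers(*cds_range))
        utr3 = int(rng.integers(*utr3_range))
        n_introns = int(rng.integers(0, max_introns + 1))
        intron_lens = [int(rng.integers(*intron_range)) for _ in range(n_introns)]

        # split CDS into n_introns + 1 chunks
        cuts = sorted(rng.choice(np.arange(50, max(cds - 50, 51)),
                                 size=n_introns, replace=False).tolist()) if n_introns else []
        chunks = [cds] if not cuts else None
        if cuts:
            bounds = [0, *cuts, cds]
            chunks = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]

        # genomic order 5'->3' on + strand; reversed block order on - strand
        blocks: list[tuple[str, int]] = [("five_prime_utr", utr5)]
        for i, ch in enumerate(chunks):
            blocks.append(("cds", ch))
            if i < len(intron_lens):
                blocks.append(("intron", intron_lens[i]))
        blocks.append(("three_prime_utr", utr3))
        if strand == "-":
            blocks = blocks[::-1]

        gm = GeneModel(gene_id=gene_id, transcript_id=f"{gene_id}.1", chrom=chrom, strand=strand)
        cur = pos
        for region, length in blocks:
            gm.regions.setdefault(region, []).append((cur, cur + length))
            cur += length
        pos = cur + gap
        models[gene_id] = gm
    return models


def synth_eclip(
    gene_models: Mapping[str, GeneModel],
    rbp_names: Sequence[str],
    background_density: float = 4.0,
    de_genes: Sequence[str] = (),
    enriched_rbps: Mapping[str, float] | None = None,
    site_length: int = 40,
    seed: int = 0,
) -> tuple[list[BindingSite], pd.DataFrame]:
    """3'UTR binding sites at a uniform per-kb density with planted enrichment.

    Non-enriched RBPs place Poisson numbers of sites uniformly per kb of
    3'UTR in every gene; enriched RBPs multiply their density by the
    planted fold within the DE genes' 3'UTRs only.
    """
    enriched_rbps = dict(enriched_rbps or {})
    if any(f < 0 for f in enriched_rbps.values()):
        raise ValueError("enrichment folds must be >= 0")
    unknown = set(de_genes) - set(gene_models)
    if unknown:
        raise KeyError(f"unknown DE genes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    de_set = set(de_genes)
    sites: list[BindingSite] = []
    truth_rows = []
    for rbp in rbp_names:
        fold = enriched_rbps.get(rbp, 1.0)
        for gene_id in sorted(gene_models):
            gm = gene_models[gene_id]
            ivs = gm.regions.get("three_prime_utr", [])
            kb = sum(e - s for s, e in ivs) / 1000.0
            if kb <= 0:
                continue
            lam = background_density * kb * (fold if gene_id in de_set else 1.0)
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            lens = np.array([e - s for s, e in ivs], float)
            which = rng.choice(len(ivs), size=n, p=lens / lens.sum())
            for iv_idx in which:
                s, e = ivs[iv_idx]
                width = min(site_length, e - s)
                start = int(rng.integers(s, max(e - width, s) + 1))
                sites.append(
                    BindingSite(
                        rbp=rbp,
                        interval=GenomicInterval(gm.chrom, start, start + width, gm.strand),
                        score=float(rng.uniform(1, 1000)),
                    )
                )
        truth_rows.append(
            dict(entity_id=rbp, entity_kind="rbp", is_positive=fold != 1.0,
                 effect_size=fold - 1.0 if fold != 1.0 else 0.0,
                 params=_params_str({"fold": fold}))
        )
    return sites, truth_frame(truth_rows)


# ---------------------------------------------------------------------------
# CETSA soluble-fraction tables
# ---------------------------------------------------------------------------

def synth_cetsa(
    n_proteins: int,
    target_amplitudes: Mapping[str, float] | None = None,
    ec50s: Mapping[str, float] | None = None,
    hills: Mapping[str, float] | None = None,
    noise_cv: float = 0.05,
    concentrations_um: Sequence[float] = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0),
    n_reps: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format CETSA table: flat non-targets, log-logistic shifted targets.

    Target proteins follow ``1 + A / (1 + (ec50/c)^h)``; everything gets
    multiplicative Gaussian noise of the stated CV (clipped at zero).
    Protein ids are P0000..; amplitude/ec50 maps may name any of them.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    target_amplitudes = dict(target_amplitudes or {})
    ec50s = dict(ec50s or {})
    hills = dict(hills or {})
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations_um, float)
    rows, truth_rows = [], []
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    unknown = (set(target_amplitudes) | set(ec50s) | set(hills)) - set(proteins)
    if unknown:
        raise KeyError(f"unknown protein ids: {sorted(unknown)}")
    for pid in proteins:
        amp = float(target_amplitudes.get(pid, 0.0))
        ec50 = float(ec50s.get(pid, 3.0))
        h = float(hills.get(pid, 1.0))
        clean = 1.0 + amp / (1.0 + (ec50 / conc) ** h)
        for rep in range(n_reps):
            noisy = clean * (1.0 + noise_cv * rng.standard_normal(conc.size))
            for c, y in zip(conc, np.clip(noisy, 0.0, None)):
                rows.append(
                    dict(protein=pid, concentration_uM=float(c), replicate=rep + 1,
                         soluble_fraction=float(y))
                )
        truth_rows.append(
            dict(entity_id=pid, entity_kind="protein", is_positive=amp != 0.0,
                 effect_size=amp, params=_params_str({"ec50_uM": ec50, "hill": h}))
        )
    return pd.DataFrame(rows), truth_frame(truth_rows)


# ---------------------------------------------------------------------------
# mRNA / RPF count matrices
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float, n_cols: int) -> np.ndarray:
    mean = np.asarray(mean, float)[:, None] * np.ones(n_cols)
    if alpha <= 1e-8:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def synth_ribo(
    n_genes: int,
    n_stabilized_repressed: int,
    mrna_lfc: float = 1.5,
    rpf_lfc: float = 0.0,
    dispersion: float = 0.05,
    n_reps: int = 3,
    mean_log: float = np.log(300.0),
    mean_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.DataFrame]:
    """Paired mRNA / RPF count matrices with stabilized-but-repressed genes.

    Affected genes gain ``mrna_lfc`` log2 units of mRNA while their RPF
    counts change by ``rpf_lfc`` (0 by default): the transcript
    accumulates but ribosome loading does not follow, i.e. translational
    efficiency drops.  Counts are negative binomial with variance
    ``mu + dispersion * mu^2``.
    """
    if n_stabilized_repressed > n_genes:
        raise ValueError("n_stabilized_repressed must be <= n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    affected = set(rng.choice(n_genes, n_stabilized_repressed, replace=False).tolist())
    base_mu = rng.lognormal(mean_log, mean_sd, n_genes)
    is_aff = np.array([i in affected for i in range(n_genes)])
    mats = {}
    for assay, lfc in (("mrna", mrna_lfc), ("rpf", rpf_lfc)):
        mu_tr = base_mu * np.where(is_aff, 2.0**lfc, 1.0)
        ctrl = _nb_counts(rng, base_mu, dispersion, n_reps)
        trt = _nb_counts(rng, mu_tr, dispersion, n_reps)
        cols = [f"{assay}_ctrl_{r+1}" for r in range(n_reps)] + [
            f"{assay}_trt_{r+1}" for r in range(n_reps)
        ]
        mats[assay] = pd.DataFrame(
            np.concatenate([ctrl, trt], axis=1), index=genes, columns=cols
        )
    condition = pd.Series(
        {
            c: ("control" if "_ctrl_" in c else "treated")
            for assay in mats for c in mats[assay].columns
        }
    )
    truth = truth_frame(
        [
            dict(entity_id=g, entity_kind="gene", is_positive=bool(a),
                 effect_size=float(mrna_lfc - rpf_lfc) if a else 0.0,
                 params=_params_str({"mrna_lfc": mrna_lfc if a else 0.0,
                                     "rpf_lfc": rpf_lfc if a else 0.0}))
            for g, a in zip(genes, is_aff)
        ]
    )
    return mats["mrna"], mats["rpf"], condition, truth


# ---------------------------------------------------------------------------
# Viability dose-response panel + dependency scores
# ---------------------------------------------------------------------------

DOSE_PANEL_CONCENTRATIONS_UM = tuple(30.0 / 3.16**k for k in range(10))


def synth_dose_panel(
    n_lines: int = 43,
    responsive_fraction: float = 0.3,
    ec50_ranges: Mapping[str, tuple[float, float]] | None = None,
    hill_ranges: Mapping[str, tuple[float, float]] | None = None,
    dependency_effect: float = 0.4,
    noise_cv: float = 0.05,
    bottom_range: tuple[float, float] = (0.05, 0.25),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Viability curves (10-point, 3.16-fold from 30 uM) plus dependency table.

    Responsive lines draw low EC50s and hill slopes inside the standard
    responsiveness window; non-responsive lines have EC50 above the tested
    range and shallow slopes.  Dependency scores (CRISPR-style, more
    negative = more dependent) for the probed gene are shifted by
    ``dependency_effect`` in the responsive group.
    """
    if not 0.0 <= responsive_fraction <= 1.0:
        raise ValueError("responsive_fraction must be in [0, 1]")
    ec50_ranges = dict(ec50_ranges or {"responsive": (0.3, 3.0), "non_responsive": (15.0, 120.0)})
    hill_ranges = dict(hill_ranges or {"responsive": (-3.2, -1.2), "non_responsive": (-0.9, -0.4)})
    rng = np.random.default_rng(seed)
    conc = np.asarray(DOSE_PANEL_CONCENTRATIONS_UM)
    n_resp = int(round(n_lines * responsive_fraction))
    rows, dep_rows, truth_rows = [], [], []
    for i in range(n_lines):
        responsive = i < n_resp
        group = "responsive" if responsive else "non_responsive"
        line = f"CL{i:03d}"
        lo, hi = ec50_ranges[group]
        ec50 = float(rng.uniform(lo, hi))
        hlo, hhi = hill_ranges[group]
        hill = float(rng.uniform(hlo, hhi))
        bottom = float(rng.uniform(*bottom_range))
        clean = bottom + (1.0 - bottom) / (1.0 + (conc / ec50) ** (-hill))
        noisy = np.clip(clean * (1.0 + noise_cv * rng.standard_normal(conc.size)), 0.0, None)
        for c, v in zip(conc, noisy):
            rows.append(dict(cell_line=line, concentration_uM=float(c), viability=float(v)))
        dep = float(rng.normal(-0.1 - (dependency_effect if responsive else 0.0), 0.15))
        dep_rows.append(dict(cell_line=line, gene="RBM42", score=dep))
        truth_rows.append(
            dict(entity_id=line, entity_kind="cell_line",
                 is_positive=bool(responsive and dependency_effect != 0),
                 effect_size=dependency_effect if responsive else 0.0,
                 params=_params_str({"ec50_uM": ec50, "hill": hill, "bottom": bottom,
                                     "responsive": float(responsive)}))
        )
    return pd.DataFrame(rows), pd.DataFrame(dep_rows), truth_frame(truth_rows)


# ---------------------------------------------------------------------------
# Channel-level imaging cells (bleedthrough controls and FRET plates)
# ---------------------------------------------------------------------------

def synth_control_cells(
    n_cells: int = 500,
    beta: float = 0.25,
    alpha: float = 0.1,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Donor-only and acceptor-only control cells for bleedthrough estimation.

    Single-label cells have no sensitized emission: the FRET channel sees
    only bleedthrough (beta * I_DD or alpha * I_AA) with multiplicative
    noise.
    """
    rng = np.random.default_rng(seed)

    def one(kind: str) -> pd.DataFrame:
        main = rng.lognormal(np.log(2000.0), 0.4, n_cells)
        other = rng.lognormal(np.log(20.0), 0.3, n_cells)  # residual background
        coeff = beta if kind == "donor_only" else alpha
        i_da = coeff * main * (1.0 + noise_cv * rng.standard_normal(n_cells))
        df = pd.DataFrame(
            {
                "well_id": kind,
                "cell_id": [f"{kind}:C{i:04d}" for i in range(n_cells)],
                "I_DD": main if kind == "donor_only" else other,
                "I_AA": other if kind == "donor_only" else main,
                "I_DA": np.clip(i_da, 0.0, None),
                "role": kind,
            }
        )
        return df

    return one("donor_only"), one("acceptor_only")


def synth_fret_plate(
    n_null_wells: int = 60,
    n_active_wells: int = 6,
    cells_per_well: int = 150,
    beta: float = 0.25,
    alpha: float = 0.1,
    fret_efficiency: float = 0.15,
    active_effect: float = 0.5,
    well_cv: float = 0.05,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Channel-level plate: I_DD / I_AA / I_DA per cell with active wells.

    The FRET channel mixes true sensitized emission — a per-well
    efficiency times total labeled-tRNA signal — with donor and acceptor
    bleedthrough.  Active (compound) wells have their FRET efficiency
    reduced by ``active_effect`` (fractional), emulating selective
    translation inhibition of the reporter pair.
    """
    rng = np.random.default_rng(seed)
    frames, truth_rows = [], []
    for w in range(n_null_wells + n_active_wells):
        active = w >= n_null_wells
        well_id = f"W{w:05d}"
        n_cells = max(5, int(rng.poisson(cells_per_well)))
        eff = fret_efficiency * (1.0 + well_cv * rng.standard_normal())
        if active:
            eff *= 1.0 - active_effect
        i_dd = rng.lognormal(np.log(2000.0), 0.4, n_cells)
        i_aa = rng.lognormal(np.log(1800.0), 0.4, n_cells)
        sens = eff * (i_dd + i_aa)
        i_da = (beta * i_dd + alpha * i_aa + sens) * (
            1.0 + noise_cv * rng.standard_normal(n_cells)
        )
        frames.append(
            pd.DataFrame(
                {
                    "well_id": well_id,
                    "cell_id": [f"{well_id}:C{i:04d}" for i in range(n_cells)],
                    "I_DD": i_dd,
                    "I_AA": i_aa,
                    "I_DA": np.clip(i_da, 0.0, None),
                    "role": "compound" if active else "dmso",
                }
            )
        )
        truth_rows.append(
            dict(entity_id=well_id, entity_kind="well", is_positive=active,
                 effect_size=active_effect if active else 0.0,
                 params=_params_str({"fret_efficiency": eff, "n_cells": n_cells}))
        )
    return pd.concat(frames, ignore_index=True), truth_frame(truth_rows)
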