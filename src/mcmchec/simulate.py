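"""Synthetic genome and data generator with known ground truth.

Builds a small multi-chromosome genome carrying every feature the
analysis stages look for, so the whole pipeline is testable offline:

* origins planted in intergenic nucleosome-free regions (NFRs), with
  per-origin abundances log-uniform over ~3 decades;
* an ACS 17-mer sampled position-wise from the packaged probability
  matrix at ~35 bp from each planted Mcm midpoint, oriented so that with
  configurable probability the Mcm site lies downstream of the ACS, and
  with configurable probability a second, opposite-strand ACS on the
  other flank;
* strand-asymmetric G/C composition around each midpoint (C excess
  upstream, G excess downstream on Watson) whose amplitude decays with
  planted abundance, mimicking the deamination footprint of replication;
* genes tiling the rest of the sequence with lognormal expression, and
  nucleosomes every ~165 bp outside NFRs;
* Mcm-protected ~61 bp fragments at each origin in numbers proportional
  to abundance, plus nucleosome-derived background fragments (mostly
  ~167 bp, with a minority subnucleosomal ~80 bp tail from partial
  digestion) whose rate scales with host-gene expression;
* ssDNA- and BrdU-like tracks whose per-origin bump amplitude is
  proportional to the planted licensed fraction, and a nucleosome-dyad
  track that is exactly zero inside NFRs.

Motif sharpness and skew amplitude share one per-origin strength factor,
log10(abundance) / decades, so every origin hallmark decays together
down the rank list the way the real data's hallmarks do.

All randomness derives from ``SimConfig.seed`` through per-stage
``numpy`` generators; a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    AcsRecord,
    FragmentRecord,
    GeneRecord,
    GenomeAssembly,
    SignalTrack,
    write_acs_table,
    write_bedgraph,
    write_fasta,
    write_fragments,
    write_gene_table,
    write_intervals,
)
from .motif import BASES, PWM_WIDTH, load_pwm, revcomp

_BASE_ARR = np.array(list(BASES))


@dataclass
class SimConfig:
    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 300_000
    gc_content: float = 0.38
    # origins
    n_origins: int = 150
    abundance_decades: float = 3.0
    min_origin_spacing: int = 2500
    edge_margin: int = 5000
    # Mcm fragments
    frags_per_abundance: float = 3.0
    mcm_frag_len: int = 61
    mcm_frag_len_sd: float = 4.0
    mcm_center_jitter_sd: float = 8.0
    # ACS planting
    acs_offset: int = 35
    downstream_prob: float = 0.8
    double_acs_prob: float = 0.6
    # chromatin
    nfr_width: int = 150
    nuc_spacing: int = 165
    nuc_frag_len: float = 167.0
    nuc_frag_len_sd: float = 8.0
    subnuc_frag_prob: float = 0.15
    subnuc_frag_len: float = 80.0
    subnuc_frag_len_sd: float = 10.0
    background_nuc_rate: float = 3.0
    expression_coupling: float = 0.2
    nuc_center_jitter_sd: float = 10.0
    # dyad chemical-cleavage emulation
    dyad_rate: float = 5.0
    dyad_frag_len: int = 51
    dyad_frag_len_sd: float = 2.0
    # GC skew
    skew_amplitude: float = 0.3
    skew_halfwidth: int = 200
    # genes
    gene_len_mean: float = 1500.0
    gene_len_sd: float = 400.0
    gene_gap_mean: float = 250.0
    expression_mu: float = 1.5
    expression_sigma: float = 1.0
    # replication tracks
    max_licensed_fraction: float = 0.9
    ssdna_gain: float = 3.0
    ssdna_baseline: float = 1.0
    ssdna_sigma: float = 500.0
    ssdna_noise_sd: float = 0.05
    # decoy peaks inside the emitted rDNA-like exclusion interval
    n_rdna_decoys: int = 2
    rdna_decoy_abundance: float = 300.0

    def __post_init__(self) -> None:
        for p in (self.downstream_prob, self.double_acs_prob,
                  self.subnuc_frag_prob, self.max_licensed_fraction,
                  self.gc_content):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.chrom_length, self.n_origins, self.nfr_width,
               self.nuc_spacing, self.skew_halfwidth) <= 0:
            raise ValueError("lengths and counts must be positive")


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    origins: pd.DataFrame  # chrom, midpoint, abundance, planted_rank, strength,
    #                        acs/skew/licensing columns, category
    genes: list[GeneRecord]
    acs_sites: list[AcsRecord]
    nucleosomes: dict[str, np.ndarray]  # dyad center coordinates per chrom
    exclusions: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _place_origins(config: SimConfig, rng: np.random.Generator):
    """One origin per equal-width slot, jittered inside the slot so the
    minimum spacing holds by construction."""
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    per = [config.n_origins // config.n_chroms] * config.n_chroms
    for i in range(config.n_origins % config.n_chroms):
        per[i] += 1
    placements: list[tuple[str, int]] = []
    for chrom, k in zip(chroms, per):
        usable = config.chrom_length - 2 * config.edge_margin
        slot = usable / k
        if slot < config.min_origin_spacing:
            raise ValueError(
                f"{k} origins on a {config.chrom_length} bp chromosome cannot "
                f"keep {config.min_origin_spacing} bp spacing"
            )
        pad = config.min_origin_spacing / 2
        for j in range(k):
            lo = config.edge_margin + j * slot + pad
            hi = config.edge_margin + (j + 1) * slot - pad
            placements.append((chrom, int(rng.uniform(lo, hi))))
    return chroms, placements


def _sample_motif(strength: float, pwm_probs: np.ndarray,
                  rng: np.random.Generator) -> str:
    """17-mer sampled position-wise from strength*PWM + (1-strength)*uniform."""
    mix = strength * pwm_probs + (1.0 - strength) * 0.25
    idx = [rng.choice(4, p=mix[i] / mix[i].sum()) for i in range(PWM_WIDTH)]
    return "".join(BASES[i] for i in idx)


def build_genome(config: SimConfig) -> tuple[GenomeAssembly, SimTruth]:
    pwm = load_pwm()
    rng = _rng(config, 0)
    chroms, placements = _place_origins(config, rng)

    # background sequence
    p = [(1 - config.gc_content) / 2, config.gc_content / 2,
         config.gc_content / 2, (1 - config.gc_content) / 2]  # A C G T
    seqs = {
        c: rng.choice(4, size=config.chrom_length, p=p).astype(np.int8)
        for c in chroms
    }

    # per-origin abundances, strengths, licensing
    n = len(placements)
    abundance = 10.0 ** rng.uniform(0.0, config.abundance_decades, size=n)
    order = np.argsort(-abundance)
    planted_rank = np.empty(n, dtype=int)
    planted_rank[order] = np.arange(1, n + 1)
    strength = np.clip(np.log10(abundance) / config.abundance_decades, 0.05, 1.0)
    licensed = config.max_licensed_fraction * abundance / abundance.max()

    acs_sites: list[AcsRecord] = []
    rows = []
    code = {b: i for i, b in enumerate(BASES)}

    for i, (chrom, mid) in enumerate(placements):
        s = seqs[chrom]
        amp = config.skew_amplitude * strength[i]
        # strand-asymmetric G/C composition: C excess upstream of the
        # midpoint, G excess downstream (Watson strand), A/T untouched
        lo = max(mid - config.skew_halfwidth, 0)
        hi = min(mid + config.skew_halfwidth + 1, len(s))
        for a, b, g_prob in ((lo, mid, (1 - amp) / 2), (mid, hi, (1 + amp) / 2)):
            region = s[a:b]
            is_gc = (region == 1) | (region == 2)
            n_gc = int(is_gc.sum())
            new = np.where(rng.random(n_gc) < g_prob, 2, 1).astype(np.int8)
            region[is_gc] = new
            s[a:b] = region

        # ACS planting: the motif center sits acs_offset bp from the Mcm
        # midpoint; orientation decides whether Mcm is downstream of it
        downstream = bool(rng.random() < config.downstream_prob)
        watson_primary = bool(rng.random() < 0.5)
        if watson_primary:
            # Watson-strand ACS: downstream of it = larger coordinates
            acs_mid = mid - config.acs_offset if downstream else mid + config.acs_offset
            acs_strand = "+"
        else:
            # Crick-strand ACS: downstream of it = smaller coordinates
            acs_mid = mid + config.acs_offset if downstream else mid - config.acs_offset
            acs_strand = "-"
        motif = _sample_motif(strength[i], pwm.probs, rng)
        planted_seq = motif if acs_strand == "+" else revcomp(motif)
        w0 = acs_mid - PWM_WIDTH // 2
        s[w0 : w0 + PWM_WIDTH] = [code[b] for b in planted_seq]
        acs_sites.append(AcsRecord(chrom, acs_mid, acs_strand))

        double = bool(rng.random() < config.double_acs_prob)
        acs2_mid = acs2_strand = None
        if double:
            # mirror ACS on the opposite flank and strand, also pointing
            # at the Mcm site
            acs2_mid = 2 * mid - acs_mid
            acs2_strand = "-" if acs_strand == "+" else "+"
            motif2 = _sample_motif(strength[i], pwm.probs, rng)
            planted2 = motif2 if acs2_strand == "+" else revcomp(motif2)
            w0 = acs2_mid - PWM_WIDTH // 2
            s[w0 : w0 + PWM_WIDTH] = [code[b] for b in planted2]
            acs_sites.append(AcsRecord(chrom, acs2_mid, acs2_strand))

        rows.append(
            {
                "chrom": chrom,
                "midpoint": mid,
                "abundance": abundance[i],
                "planted_rank": planted_rank[i],
                "strength": strength[i],
                "acs_midpoint": acs_mid,
                "acs_strand": acs_strand,
                "mcm_downstream_of_acs": downstream,
                "double_acs": double,
                "acs2_midpoint": acs2_mid if double else -1,
                "skew_amplitude": amp,
                "licensed_fraction": licensed[i],
                "category": "origin",
            }
        )

    origins = pd.DataFrame(rows)

    # exclusion-zone features: an rDNA-like interval with decoy peaks on
    # the last chromosome, and Ty-like intervals with no special signal
    exclusions: dict[str, list[tuple[str, int, int]]] = {"rdna": [], "ty": []}
    if config.n_rdna_decoys > 0:
        # drop the decoys into the widest gap between genuine origins so
        # the exclusion interval never swallows a real origin
        chrom = chroms[-1]
        mids = np.sort(origins.loc[origins.chrom == chrom, "midpoint"].to_numpy())
        gaps = np.diff(mids)
        gi = int(np.argmax(gaps))
        m1, m2 = int(mids[gi]), int(mids[gi + 1])
        decoy_gap = 1200  # > zero_radius*2 + refine slack: distinct peaks
        margin = config.min_origin_spacing // 2 + 200
        decoy_rows = []
        pos = m1 + margin
        for _ in range(config.n_rdna_decoys):
            if pos > m2 - margin:
                break
            decoy_rows.append(
                {
                    "chrom": chrom, "midpoint": pos,
                    "abundance": config.rdna_decoy_abundance,
                    "planted_rank": -1, "strength": 1.0,
                    "acs_midpoint": -1, "acs_strand": "+",
                    "mcm_downstream_of_acs": False, "double_acs": False,
                    "acs2_midpoint": -1, "skew_amplitude": 0.0,
                    "licensed_fraction": 0.0, "category": "rdna",
                }
            )
            pos += decoy_gap
        if decoy_rows:
            lo = decoy_rows[0]["midpoint"] - 600
            hi = decoy_rows[-1]["midpoint"] + 600
            origins = pd.concat([origins, pd.DataFrame(decoy_rows)],
                                ignore_index=True)
            exclusions["rdna"].append((chrom, lo, hi))
    ty_chrom = chroms[0]
    exclusions["ty"].append((ty_chrom, 2000, 2300))

    # nucleosome dyads: phased every nuc_spacing, excluded from NFRs
    nfr_keepout = config.nfr_width // 2 + 70  # dyad cannot sit this close
    nucleosomes: dict[str, np.ndarray] = {}
    all_mids = origins.groupby("chrom")["midpoint"].apply(np.asarray).to_dict()
    for chrom in chroms:
        centers = np.arange(config.nuc_spacing, config.chrom_length - config.nuc_spacing,
                            config.nuc_spacing)
        mids = all_mids.get(chrom, np.empty(0))
        if len(mids):
            d = np.abs(centers[:, None] - mids[None, :]).min(axis=1)
            centers = centers[d > nfr_keepout]
        nucleosomes[chrom] = centers

    # genes tile the sequence, skipping origin NFRs so origins stay intergenic
    rng_g = _rng(config, 1)
    genes: list[GeneRecord] = []
    forbid_pad = config.nfr_width // 2 + 20
    for chrom in chroms:
        mids = np.sort(all_mids.get(chrom, np.empty(0)))
        pos = 200
        while True:
            glen = int(np.clip(rng_g.normal(config.gene_len_mean, config.gene_len_sd),
                               500, 3000))
            gap = int(rng_g.exponential(config.gene_gap_mean)) + 100
            start, end = pos, pos + glen
            if end > config.chrom_length - 200:
                break
            # does the gene body invade an origin NFR?
            clash = mids[(mids >= start - forbid_pad) & (mids < end + forbid_pad)]
            if len(clash):
                pos = int(clash[-1]) + forbid_pad + 1
                continue
            strand = "+" if rng_g.random() < 0.5 else "-"
            expr = float(rng_g.lognormal(config.expression_mu, config.expression_sigma))
            genes.append(GeneRecord(chrom, start, end, strand, expr))
            pos = end + gap

    sequence = {c: "".join(_BASE_ARR[seqs[c]]) for c in chroms}
    assembly = GenomeAssembly(tuple(chroms),
                              {c: config.chrom_length for c in chroms}, sequence)
    truth = SimTruth(origins, genes, acs_sites, nucleosomes, exclusions)
    return assembly, truth


def _covering_expression(truth: SimTruth, chrom: str, pos: np.ndarray) -> np.ndarray:
    """Expression of the gene covering each position (0 when intergenic)."""
    genes = [g for g in truth.genes if g.chrom == chrom]
    starts = np.array([g.start for g in genes])
    ends = np.array([g.end for g in genes])
    exprs = np.array([g.expression for g in genes])
    out = np.zeros(len(pos))
    if len(genes) == 0:
        return out
    idx = np.searchsorted(starts, pos, side="right") - 1
    valid = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
    out[valid] = exprs[idx[valid]]
    return out


def sample_fragments(config: SimConfig, truth: SimTruth) -> list[FragmentRecord]:
    """Mcm fragments at planted origins plus nucleosome background.

    Per-origin counts are Poisson with mean abundance * frags_per_abundance;
    nucleosome counts are Poisson with a rate that grows with host-gene
    expression (transcribed chromatin is digested more).
    """
    rng = _rng(config, 2)
    frags: list[FragmentRecord] = []
    L = config.chrom_length

    for row in truth.origins.itertuples(index=False):
        count = rng.poisson(row.abundance * config.frags_per_abundance)
        centers = row.midpoint + np.round(
            rng.normal(0, config.mcm_center_jitter_sd, count)
        ).astype(int)
        lens = np.clip(
            np.round(rng.normal(config.mcm_frag_len, config.mcm_frag_len_sd, count)),
            20, 200,
        ).astype(int)
        starts = np.clip(centers - lens // 2, 0, None)
        ends = np.minimum(starts + lens, L)
        frags.extend(
            FragmentRecord(row.chrom, int(s), int(e))
            for s, e in zip(starts, ends) if e - s >= 1
        )

    for chrom, centers in truth.nucleosomes.items():
        expr = _covering_expression(truth, chrom, centers)
        rates = config.background_nuc_rate * (1.0 + config.expression_coupling * expr)
        counts = rng.poisson(rates)
        for center, k in zip(centers, counts):
            if k == 0:
                continue
            sub = rng.random(k) < config.subnuc_frag_prob
            lens = np.where(
                sub,
                rng.normal(config.subnuc_frag_len, config.subnuc_frag_len_sd, k),
                rng.normal(config.nuc_frag_len, config.nuc_frag_len_sd, k),
            )
            lens = np.clip(np.round(lens), 20, 250).astype(int)
            cs = center + np.round(
                rng.normal(0, config.nuc_center_jitter_sd, k)
            ).astype(int)
            starts = np.clip(cs - lens // 2, 0, None)
            ends = np.minimum(starts + lens, L)
            frags.extend(
                FragmentRecord(chrom, int(s), int(e))
                for s, e in zip(starts, ends) if e - s >= 1
            )
    return frags


def sample_dyad_fragments(config: SimConfig, truth: SimTruth) -> list[FragmentRecord]:
    """Chemical-cleavage-style ~51 bp dyad-core fragments at nucleosome
    centers (the 46-56 bp class used for nucleosome mapping)."""
    rng = _rng(config, 3)
    frags: list[FragmentRecord] = []
    for chrom, centers in truth.nucleosomes.items():
        counts = rng.poisson(config.dyad_rate, len(centers))
        for center, k in zip(centers, counts):
            if k == 0:
                continue
            lens = np.clip(
                np.round(rng.normal(config.dyad_frag_len, config.dyad_frag_len_sd, k)),
                46, 56,
            ).astype(int)
            cs = center + np.round(rng.normal(0, 2.0, k)).astype(int)
            starts = np.clip(cs - lens // 2, 0, None)
            ends = np.minimum(starts + lens, config.chrom_length)
            frags.extend(
                FragmentRecord(chrom, int(s), int(e))
                for s, e in zip(starts, ends) if e - s >= 1
            )
    return frags


def emit_tracks(
    config: SimConfig, truth: SimTruth, assembly: GenomeAssembly
) -> tuple[SignalTrack, SignalTrack, SignalTrack]:
    """(ssDNA-like, nucleosome-dyad, BrdU-like) tracks.

    ssDNA/BrdU: baseline plus a Gaussian bump per origin with amplitude
    proportional to the planted licensed fraction, plus iid noise. Dyad:
    a compact triangular kernel at each nucleosome center — exactly zero
    inside NFRs because no dyads were placed there.
    """
    rng = _rng(config, 4)
    ssdna = SignalTrack.zeros(assembly)
    brdu = SignalTrack.zeros(assembly)
    dyad = SignalTrack.zeros(assembly)

    for chrom in assembly.chrom_names:
        n = assembly.length(chrom)
        x = np.arange(n)
        base = np.full(n, config.ssdna_baseline)
        bump = np.zeros(n)
        sub = truth.origins[truth.origins.chrom == chrom]
        for row in sub.itertuples(index=False):
            amp = config.ssdna_gain * row.licensed_fraction
            if amp <= 0:
                continue
            lo = max(row.midpoint - int(4 * config.ssdna_sigma), 0)
            hi = min(row.midpoint + int(4 * config.ssdna_sigma) + 1, n)
            d = x[lo:hi] - row.midpoint
            bump[lo:hi] += amp * np.exp(-0.5 * (d / config.ssdna_sigma) ** 2)
        noise = (rng.normal(0, config.ssdna_noise_sd, n)
                 if config.ssdna_noise_sd > 0 else 0.0)
        noise2 = (rng.normal(0, config.ssdna_noise_sd, n)
                  if config.ssdna_noise_sd > 0 else 0.0)
        ssdna.values[chrom] = base + bump + noise
        brdu.values[chrom] = base + 0.8 * bump + noise2

        half = 30  # compact kernel: zero beyond 30 bp of a dyad
        kernel = 1.0 - np.abs(np.arange(-half, half + 1)) / (half + 1)
        d = np.zeros(n)
        for center in truth.nucleosomes[chrom]:
            lo, hi = center - half, center + half + 1
            if lo < 0 or hi > n:
                continue
            d[lo:hi] += kernel
        dyad.values[chrom] = d
    return ssdna, dyad, brdu


def simulate(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate one complete dataset and write every pipeline input.

    Returns a name -> path mapping for genome.fa, fragments.bed,
    dyad_fragments.bed, genes.tsv, acs.tsv, ssdna.bedgraph,
    dyads.bedgraph, brdu.bedgraph, exclusions_rdna.bed,
    exclusions_ty.bed and truth.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assembly, truth = build_genome(config)
    frags = sample_fragments(config, truth)
    dyad_frags = sample_dyad_fragments(config, truth)
    ssdna, dyad, brdu = emit_tracks(config, truth, assembly)

    paths = {name: outdir / name for name in (
        "genome.fa", "fragments.bed", "dyad_fragments.bed", "genes.tsv",
        "acs.tsv", "ssdna.bedgraph", "dyads.bedgraph", "brdu.bedgraph",
        "exclusions_rdna.bed", "exclusions_ty.bed", "truth.tsv",
    )}
    write_fasta(assembly, paths["genome.fa"])
    write_fragments(frags, paths["fragments.bed"])
    write_fragments(dyad_frags, paths["dyad_fragments.bed"])
    write_gene_table(truth.genes, paths["genes.tsv"])
    write_acs_table(truth.acs_sites, paths["acs.tsv"])
    write_bedgraph(ssdna, paths["ssdna.bedgraph"])
    write_bedgraph(dyad, paths["dyads.bedgraph"])
    write_bedgraph(brdu, paths["brdu.bedgraph"])
    write_intervals(truth.exclusions["rdna"], paths["exclusions_rdna.bed"])
    write_intervals(truth.exclusions["ty"], paths["exclusions_ty.bed"])
    truth.origins.to_csv(paths["truth.tsv"], sep="\t", index=False)
    return paths
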