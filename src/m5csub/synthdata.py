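"""Synthetic benchmark corpus: transcripts, m5C sites, CLIP peaks and truth.

The generator emulates the shape of a regulator-substrate study without any
download: multi-exon transcripts with a GC-biased background (60% GC, the
composition enrichment reported around m5C sites), methylated cytosines at
known spliced positions, and binding peaks placed exactly over the subset
of sites designated as true substrates.  Positive sites carry a planted
G-run immediately 3' of the centered C (emulating the NGGG motif of
NSUN2-dependent sites, with the site itself as the N) at a configurable
planting rate, so classifier signal recovery is measurable and switchable
off (planting_rate=0 gives exchangeable classes).

Site centers are kept >= ``min_separation`` nt apart so that no site's
41-nt mapping window can touch a neighboring site's peak: peak-overlap
labeling then recovers the designed truth exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq_io import GenomicSite, LabeledWindow, PeakInterval, TranscriptModel, extract_window
from . import dataset as ds_mod


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic corpus."""

    n_transcripts: int = 60
    n_exons_range: tuple[int, int] = (2, 3)
    exon_length_range: tuple[int, int] = (250, 400)
    intron_length_range: tuple[int, int] = (60, 150)
    #: background base probabilities for (A, C, G, U); 60% GC
    base_probs: tuple[float, float, float, float] = (0.2, 0.3, 0.3, 0.2)
    motif: str = "GGG"
    #: inclusive range of motif start offsets relative to the centered C
    plant_offsets: tuple[int, int] = (1, 3)
    planting_rate: float = 0.9
    n_pos: int = 500
    n_unbound: int = 100
    n_ivt: int = 0
    peak_halfwidth: int = 15
    peak_jitter: int = 0
    #: minimum distance between site centers (spliced space)
    min_separation: int = 40
    #: minimum distance of a site center from the spliced transcript ends
    margin: int = 45
    transcripts_per_chrom: int = 10
    intergenic_gap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base probabilities must sum to 1")
        if not 0.0 <= self.planting_rate <= 1.0:
            raise ValueError("planting_rate must be in [0, 1]")


@dataclass
class Corpus:
    """In-memory synthetic corpus; every component is writable to the same
    plain-text dialects the real pipeline consumes."""

    config: SimConfig
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    m5c_sites: list[GenomicSite]
    peaks: list[PeakInterval]
    ivt_sites: list[GenomicSite]
    truth: pd.DataFrame  # transcript_id, spliced_pos, genomic_pos, chrom, strand, label

    @property
    def transcripts_by_id(self) -> dict[str, TranscriptModel]:
        return {t.transcript_id: t for t in self.transcripts}

    def write(self, outdir: str) -> dict[str, str]:
        """Write genome FASTA, GTF, site/peak/blacklist BED and truth TSV."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "gtf": os.path.join(outdir, "annotation.gtf"),
            "sites": os.path.join(outdir, "m5c_sites.bed"),
            "peaks": os.path.join(outdir, "peaks.bed"),
            "ivt": os.path.join(outdir, "ivt_blacklist.bed"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        with open(paths["genome"], "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n{self.genome[chrom]}\n")
        with open(paths["gtf"], "w") as fh:
            for t in self.transcripts:
                for s, e in t.exons:
                    attrs = f'gene_id "{t.transcript_id}"; transcript_id "{t.transcript_id}";'
                    fh.write(
                        f"{t.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                    )
        with open(paths["sites"], "w") as fh:
            for s in self.m5c_sites:
                fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.name}\t.\t{s.strand}\n")
        with open(paths["peaks"], "w") as fh:
            for p in self.peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t.\t{p.strand}\n")
        with open(paths["ivt"], "w") as fh:
            for s in self.ivt_sites:
                fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.name}\t.\t{s.strand}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_seq(rng: np.random.Generator, length: int, probs) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGU", dtype="S1"), size=length, p=list(probs))


def simulate_corpus(config: SimConfig | None = None) -> Corpus:
    """Generate a deterministic corpus under ``config`` (seeded RNG)."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    # --- transcript skeletons in transcript orientation -------------------
    skeletons = []  # (tid, strand, exon_lengths, intron_lengths, premrna array)
    for i in range(config.n_transcripts):
        n_exons = int(rng.integers(config.n_exons_range[0], config.n_exons_range[1] + 1))
        exon_lengths = rng.integers(
            config.exon_length_range[0], config.exon_length_range[1] + 1, size=n_exons
        )
        intron_lengths = rng.integers(
            config.intron_length_range[0],
            config.intron_length_range[1] + 1,
            size=max(0, n_exons - 1),
        )
        strand = "+" if rng.random() < 0.5 else "-"
        pre_len = int(exon_lengths.sum() + intron_lengths.sum())
        pre = _random_seq(rng, pre_len, config.base_probs)
        skeletons.append((f"tx{i:04d}", strand, exon_lengths, intron_lengths, pre))

    # spliced-position bookkeeping per transcript
    def spliced_maps(exon_lengths, intron_lengths):
        """exon start offsets in spliced and pre-mRNA coordinates."""
        spl_starts, pre_starts = [], []
        spl, pre = 0, 0
        for k, elen in enumerate(exon_lengths):
            spl_starts.append(spl)
            pre_starts.append(pre)
            spl += int(elen)
            pre += int(elen)
            if k < len(intron_lengths):
                pre += int(intron_lengths[k])
        return spl_starts, pre_starts

    def spliced_to_pre(pos, exon_lengths, spl_starts, pre_starts):
        for k in range(len(exon_lengths) - 1, -1, -1):
            if pos >= spl_starts[k]:
                return pre_starts[k] + (pos - spl_starts[k])
        raise IndexError(pos)

    # --- choose site slots -------------------------------------------------
    slots: list[tuple[int, int]] = []  # (transcript index, spliced center)
    for ti, (_, _, exon_lengths, _, pre) in enumerate(skeletons):
        splen = int(exon_lengths.sum())
        start = config.margin
        stop = splen - config.margin
        pos = start
        while pos < stop:
            slots.append((ti, pos + int(rng.integers(0, 4))))
            pos += config.min_separation
    n_needed = config.n_pos + config.n_unbound + config.n_ivt
    if n_needed > len(slots):
        raise ValueError(
            f"requested {n_needed} sites but the corpus only supports {len(slots)}; "
            "increase n_transcripts or transcript lengths"
        )
    order = rng.permutation(len(slots))
    chosen = [slots[i] for i in order[:n_needed]]
    roles = (
        ["pos"] * config.n_pos + ["unbound"] * config.n_unbound + ["ivt"] * config.n_ivt
    )

    # --- write site centers and planted motifs into the pre-mRNA ----------
    motif = np.frombuffer(config.motif.encode(), dtype="S1")
    site_records = []  # (ti, spliced_pos, role, planted)
    maps = [spliced_maps(sk[2], sk[3]) for sk in skeletons]
    for (ti, spos), role in zip(chosen, roles):
        _, strand, exon_lengths, _, pre = skeletons[ti]
        spl_starts, pre_starts = maps[ti]
        pre[spliced_to_pre(spos, exon_lengths, spl_starts, pre_starts)] = b"C"
        planted = False
        if role in ("pos", "ivt") and rng.random() < config.planting_rate:
            offset = int(rng.integers(config.plant_offsets[0], config.plant_offsets[1] + 1))
            for m, base in enumerate(motif):
                ppos = spliced_to_pre(
                    spos + offset + m, exon_lengths, spl_starts, pre_starts
                )
                pre[ppos] = base
            planted = True
        site_records.append((ti, spos, role, planted))

    # --- lay transcripts onto chromosomes ----------------------------------
    from .seq_io import reverse_complement

    genome_parts: dict[str, list[str]] = {}
    transcripts: list[TranscriptModel] = []
    tx_offset: dict[int, tuple[str, int]] = {}
    cursor: dict[str, int] = {}
    for ti, (tid, strand, exon_lengths, intron_lengths, pre) in enumerate(skeletons):
        chrom = f"chr{ti // config.transcripts_per_chrom + 1}"
        genome_parts.setdefault(chrom, [])
        offset = cursor.get(chrom, 0)
        pre_str = pre.tobytes().decode()
        genomic_seg = pre_str if strand == "+" else reverse_complement(pre_str)
        genome_parts[chrom].append(genomic_seg)
        gap = _random_seq(rng, config.intergenic_gap, config.base_probs)
        genome_parts[chrom].append(gap.tobytes().decode())
        tx_offset[ti] = (chrom, offset)
        cursor[chrom] = offset + len(pre_str) + config.intergenic_gap

        # exon intervals in genomic coordinates
        _, pre_starts = spliced_maps(exon_lengths, intron_lengths)
        exons = []
        T = len(pre_str)
        for k, elen in enumerate(exon_lengths):
            s_t, e_t = pre_starts[k], pre_starts[k] + int(elen)
            if strand == "+":
                exons.append((offset + s_t, offset + e_t))
            else:
                exons.append((offset + T - e_t, offset + T - s_t))
        spliced = "".join(
            pre_str[pre_starts[k] : pre_starts[k] + int(elen)]
            for k, elen in enumerate(exon_lengths)
        )
        transcripts.append(
            TranscriptModel(
                tid,
                chrom,
                strand,
                sorted(exons),
                spliced_seq=spliced,
                premrna_seq=pre_str,
            )
        )
    genome = {c: "".join(parts) for c, parts in genome_parts.items()}

    # --- emit sites, peaks, truth ------------------------------------------
    def to_genomic(ti: int, spos: int) -> int:
        _, strand, exon_lengths, intron_lengths, pre = skeletons[ti]
        spl_starts, pre_starts = maps[ti]
        ppos = spliced_to_pre(spos, exon_lengths, spl_starts, pre_starts)
        chrom, offset = tx_offset[ti]
        T = len(pre)
        return offset + ppos if strand == "+" else offset + (T - 1 - ppos)

    m5c_sites, peaks, ivt_sites, truth_rows = [], [], [], []
    for idx, (ti, spos, role, planted) in enumerate(site_records):
        tid, strand = skeletons[ti][0], skeletons[ti][1]
        chrom, _ = tx_offset[ti]
        gpos = to_genomic(ti, spos)
        name = f"site{idx:05d}"
        m5c_sites.append(GenomicSite(chrom, gpos, strand, kind="m5c", name=name))
        if role in ("pos", "ivt"):
            jitter = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1)) if config.peak_jitter else 0
            start = max(0, gpos - config.peak_halfwidth + jitter)
            peaks.append(
                PeakInterval(chrom, start, gpos + config.peak_halfwidth + 1 + jitter, strand, name)
            )
        if role == "ivt":
            ivt_sites.append(GenomicSite(chrom, gpos, strand, kind="ivt_artifact", name=name))
        truth_rows.append(
            {
                "site": name,
                "transcript_id": tid,
                "spliced_pos": spos,
                "genomic_pos": gpos,
                "chrom": chrom,
                "strand": strand,
                "label": 1 if role == "pos" else 0,
                "role": role,
                "planted": planted,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return Corpus(
        config=config,
        genome=genome,
        transcripts=transcripts,
        m5c_sites=m5c_sites,
        peaks=peaks,
        ivt_sites=ivt_sites,
        truth=truth,
    )


def make_labeled_windows(
    corpus: Corpus,
    flank: int = 20,
    regulator: str = "NSUN2",
    model_kind: str = "mature_mrna",
    seed: int | None = None,
) -> tuple[list[LabeledWindow], list[LabeledWindow]]:
    """Extract labeled windows straight from the designed truth table.

    Positives come from the truth labels; negatives are same-transcript
    cytosines drawn 1:1 by the dataset module's sampler.  This bypasses the
    peak-overlap plumbing, giving classifier benchmarks direct access to
    clean labels.
    """
    rng = np.random.default_rng(corpus.seed if seed is None else seed)
    tx = corpus.transcripts_by_id
    pos_by_tx: dict[str, list[int]] = {}
    for row in corpus.truth.itertuples():
        if row.label == 1:
            spos = row.spliced_pos
            if model_kind == "full_transcript":
                spos = tx[row.transcript_id].genomic_to_premrna(row.genomic_pos)
            pos_by_tx.setdefault(row.transcript_id, []).append(int(spos))
    for tid in pos_by_tx:
        pos_by_tx[tid] = sorted(pos_by_tx[tid])
    neg_by_tx = ds_mod.sample_negatives(pos_by_tx, tx, model_kind, rng)

    def build(by_tx: dict[str, list[int]], label: int) -> list[LabeledWindow]:
        out = []
        for tid in sorted(by_tx):
            seq = tx[tid].sequence(model_kind)
            for p in by_tx[tid]:
                out.append(
                    LabeledWindow(
                        sequence=extract_window(seq, p, flank),
                        label=label,
                        transcript_id=tid,
                        regulator=regulator,
                        window_id=f"{tid}:{p}:{label}",
                        position=p,
                    )
                )
        return out

    return build(pos_by_tx, 1), build(neg_by_tx, 0)


# convenience: the corpus seed
Corpus.seed = property(lambda self: self.config.seed)  # type: ignore[attr-defined]
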