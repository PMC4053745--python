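"""Deterministic synthetic fixture generator.

Emulates the data classes that genome-browser style figures are built from,
at desk scale and with full ground truth, so no download is ever needed:

* a random reference genome (FASTA),
* multi-exon transcript models grouped by transcript id (GFF3),
* spliced short reads sampled uniformly over the transcripts, with
  splice-aware CIGARs (``xMyNzM`` across introns) and mismatches planted at
  recorded sites with recorded multiplicities (SAM),
* interval features (BED), inter/intra-chromosomal link tables and
  Manhattan-style per-position score tables (TSV),
* a toy cytoband table (TSV),
* a ``truth.json`` with the planted mismatch sites, junction counts, total
  aligned bases and transcript structures — enough to verify every stat
  output exactly.

The generator is a pure function of its :class:`FixtureSpec`: the same seed
produces byte-identical output directories.  What it does *not* emulate:
base-quality strings, sequencing-error noise beyond the planted sites,
paired ends, and strand-specific protocols.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = ["FixtureSpec", "generate_fixture"]

_BASES = np.array(["A", "C", "G", "T"])
_STAIN_CYCLE = ["gneg", "gpos25", "gpos50", "gpos75", "gpos100", "gvar"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults are chosen as a desk-scale RNA-seq-like scenario: a couple of
    ~60 kb chromosomes, a handful of 4-7 exon transcripts with 80-300 bp
    exons and 200-1500 bp introns on the first chromosome, 300 spliced
    75 bp reads, and a few planted mismatch sites.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 60_000
    n_transcripts: int = 4
    exons_per_transcript: tuple[int, int] = (4, 7)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (200, 1500)
    n_reads: int = 300
    read_length: int = 75
    n_mismatch_sites: int = 6
    n_features: int = 20
    n_links: int = 12
    n_score_positions: int = 200
    score_groups: tuple[str, ...] = ("methodA", "methodB", "methodC")
    n_cytobands: int = 6


def _rand_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _make_transcripts(spec: FixtureSpec, rng: np.random.Generator) -> list[dict]:
    """Transcript structures on chr1, laid out left to right with slack."""
    transcripts = []
    cursor = 200
    for t in range(spec.n_transcripts):
        n_ex = _rand_int(rng, *spec.exons_per_transcript)
        exons = []
        pos = cursor
        for i in range(n_ex):
            w = _rand_int(rng, *spec.exon_length)
            exons.append((pos, pos + w - 1))
            pos += w
            if i + 1 < n_ex:
                pos += _rand_int(rng, *spec.intron_length)
        if pos > spec.chrom_length - 200:
            raise ValueError(
                "infeasible fixture spec: transcripts do not fit the chromosome"
            )
        strand = "+" if t % 2 == 0 else "-"
        transcripts.append(
            {"tx_id": f"tx{t + 1}", "seqname": "chr1", "strand": strand,
             "exons": exons}
        )
        # shift the next transcript only partway so some transcripts overlap
        cursor = exons[len(exons) // 2][0] + _rand_int(rng, 50, 400)
    return transcripts


def _tx_to_genomic(exons: list[tuple[int, int]], offset: int, n: int):
    """Map a transcript-coordinate window [offset, offset+n) to genomic
    blocks (start, end) across the exon structure."""
    blocks = []
    remaining = n
    skip = offset
    for s, e in exons:
        w = e - s + 1
        if skip >= w:
            skip -= w
            continue
        bs = s + skip
        take = min(w - skip, remaining)
        blocks.append((bs, bs + take - 1))
        remaining -= take
        skip = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read window exceeds transcript length")
    return blocks


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        parts.append(f"{e - s + 1}M")
        if i + 1 < len(blocks):
            parts.append(f"{blocks[i + 1][0] - e - 1}N")
    return "".join(parts)


def generate_fixture(spec: FixtureSpec, outdir) -> dict:
    """Generate the full fixture into ``outdir`` and return paths + truth.

    Deterministic: a fixed spec (including seed) yields byte-identical
    files.  Raises on infeasible specs (e.g. reads longer than the shortest
    transcript).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]

    # reference
    ref = {
        c: "".join(rng.choice(_BASES, size=spec.chrom_length)) for c in chroms
    }
    fasta_path = outdir / "reference.fa"
    with open(fasta_path, "w") as fh:
        for c in chroms:
            fh.write(f">{c}\n")
            for i in range(0, spec.chrom_length, 70):
                fh.write(ref[c][i : i + 70] + "\n")

    # transcripts (GFF3)
    transcripts = _make_transcripts(spec, rng)
    gff_path = outdir / "genes.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in transcripts:
            s0, e0 = tx["exons"][0][0], tx["exons"][-1][1]
            fh.write(
                f"chr1\tsim\tmRNA\t{s0}\t{e0}\t.\t{tx['strand']}\t.\t"
                f"ID={tx['tx_id']}\n"
            )
            for j, (s, e) in enumerate(tx["exons"]):
                fh.write(
                    f"chr1\tsim\texon\t{s}\t{e}\t.\t{tx['strand']}\t.\t"
                    f"ID={tx['tx_id']}.e{j + 1};Parent={tx['tx_id']}\n"
                )

    # reads: uniform over transcripts, splice-aware
    tx_lengths = [sum(e - s + 1 for s, e in t["exons"]) for t in transcripts]
    if min(tx_lengths) < spec.read_length:
        raise ValueError(
            "infeasible fixture spec: read length exceeds a transcript length"
        )
    reads = []  # (qname, pos, cigar, blocks, seq list per block)
    junction_counts: dict[str, int] = {}
    for i in range(spec.n_reads):
        t = int(rng.integers(0, len(transcripts)))
        tx = transcripts[t]
        off = int(rng.integers(0, tx_lengths[t] - spec.read_length + 1))
        blocks = _tx_to_genomic(tx["exons"], off, spec.read_length)
        for (s1, e1), (s2, _) in zip(blocks, blocks[1:]):
            key = f"chr1:{e1}-{s2}"
            junction_counts[key] = junction_counts.get(key, 0) + 1
        seq = list("".join(ref["chr1"][s - 1 : e] for s, e in blocks))
        reads.append(
            {"qname": f"read{i + 1}", "pos": blocks[0][0],
             "cigar": _blocks_to_cigar(blocks), "blocks": blocks, "seq": seq}
        )

    # planted mismatches: pick covered positions, mutate EVERY covering read
    # so the planted multiplicity equals the coverage depth at the site
    cover: dict[int, list[tuple[int, int]]] = {}  # pos -> (read idx, query off)
    for ri, r in enumerate(reads):
        qoff = 0
        for s, e in r["blocks"]:
            for p in range(s, e + 1):
                cover.setdefault(p, []).append((ri, qoff + (p - s)))
            qoff += e - s + 1
    covered = sorted(cover)
    if len(covered) < spec.n_mismatch_sites:
        raise ValueError("infeasible fixture spec: too few covered positions")
    picks = rng.choice(len(covered), size=spec.n_mismatch_sites, replace=False)
    planted = []
    for k in sorted(int(p) for p in picks):
        pos = covered[k]
        ref_base = ref["chr1"][pos - 1]
        alts = [b for b in "ACGT" if b != ref_base]
        alt = alts[int(rng.integers(0, 3))]
        for ri, qo in cover[pos]:
            reads[ri]["seq"][qo] = alt
        planted.append(
            {"seqname": "chr1", "pos": pos, "ref": ref_base, "alt": alt,
             "count": len(cover[pos])}
        )

    sam_path = outdir / "reads.sam"
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for c in chroms:
            fh.write(f"@SQ\tSN:{c}\tLN:{spec.chrom_length}\n")
        for r in sorted(reads, key=lambda r: (r["pos"], r["qname"])):
            seq = "".join(r["seq"])
            fh.write(
                f"{r['qname']}\t0\tchr1\t{r['pos']}\t60\t{r['cigar']}\t*\t0\t0\t"
                f"{seq}\t*\n"
            )

    # BED features across all chromosomes
    bed_path = outdir / "features.bed"
    with open(bed_path, "w") as fh:
        for i in range(spec.n_features):
            c = chroms[int(rng.integers(0, len(chroms)))]
            s = int(rng.integers(0, spec.chrom_length - 500))
            w = int(rng.integers(50, 500))
            strand = "+-."[int(rng.integers(0, 3))]
            fh.write(f"{c}\t{s}\t{s + w}\tfeat{i + 1}\t{i}\t{strand}\n")

    # links
    links_path = outdir / "links.tsv"
    with open(links_path, "w") as fh:
        fh.write("chr1\tpos1\tchr2\tpos2\tscore\tsupport\n")
        for _ in range(spec.n_links):
            c1 = chroms[int(rng.integers(0, len(chroms)))]
            c2 = chroms[int(rng.integers(0, len(chroms)))]
            p1 = int(rng.integers(1, spec.chrom_length + 1))
            p2 = int(rng.integers(1, spec.chrom_length + 1))
            score = float(np.round(rng.random() * 10, 3))
            support = int(rng.integers(1, 50))
            fh.write(f"{c1}\t{p1}\t{c2}\t{p2}\t{score}\t{support}\n")

    # per-position scores (Manhattan-style), one row per (chrom, pos, group)
    scores_path = outdir / "scores.tsv"
    with open(scores_path, "w") as fh:
        fh.write("chr\tpos\tvalue\tgroup\n")
        for g in spec.score_groups:
            for c in chroms:
                pos = np.sort(
                    rng.choice(
                        np.arange(1, spec.chrom_length + 1),
                        size=spec.n_score_positions, replace=False,
                    )
                )
                vals = np.round(np.abs(rng.normal(0.0, 1.0, spec.n_score_positions)), 4)
                for p, v in zip(pos, vals):
                    fh.write(f"{c}\t{int(p)}\t{v}\t{g}\n")

    # cytobands
    cyto_path = outdir / "cytobands.tsv"
    with open(cyto_path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tgieStain\n")
        for c in chroms:
            edges = np.linspace(1, spec.chrom_length, spec.n_cytobands + 1).astype(int)
            mid = spec.n_cytobands // 2
            for b in range(spec.n_cytobands):
                s, e = int(edges[b]) + (1 if b else 0), int(edges[b + 1])
                stain = "acen" if b in (mid - 1, mid) else _STAIN_CYCLE[b % len(_STAIN_CYCLE)]
                fh.write(f"{c}\t{s}\t{e}\t{c}_b{b + 1}\t{stain}\n")

    truth = {
        "spec": {**asdict(spec)},
        "planted_mismatches": planted,
        "junction_counts": dict(sorted(junction_counts.items())),
        "total_aligned_bases": int(
            sum(e - s + 1 for r in reads for s, e in r["blocks"])
        ),
        "n_reads": len(reads),
        "transcripts": [
            {"tx_id": t["tx_id"], "strand": t["strand"],
             "exons": [list(x) for x in t["exons"]]}
            for t in transcripts
        ],
    }
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "fasta": fasta_path, "gff3": gff_path, "sam": sam_path,
        "bed": bed_path, "links": links_path, "scores": scores_path,
        "cytobands": cyto_path, "truth_path": truth_path, "truth": truth,
    }
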