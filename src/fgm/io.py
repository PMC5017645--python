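"""File formats: FASTA/FASTQ, pool-design/marker/F-set TSVs, .size, AGP.

Everything the pipeline writes is plain text; F-set TSVs are emitted in
lexicographic element order so identical runs are byte-identical.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import dna
from .features import FSet
from .physmap import PhysContig
from .simulate import Clone, ErrorModel, Genome, Marker, ReadBatch


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    with _open(path) as fh:
        return {r.id: str(r.seq).upper() for r in SeqIO.parse(fh, "fasta")}


def write_genome_fasta(genome: Genome, path) -> None:
    write_fasta({c: dna.decode(codes) for c, codes in genome.sequences.items()}, path)


def read_genome_fasta(path) -> Genome:
    return Genome.from_strings(read_fasta(path))


# ---------------------------------------------------------------------------
# FASTQ (Sanger Phred+33)


def write_pool_fastq(batch: ReadBatch, out_dir, error_model: ErrorModel | None = None) -> tuple[Path, Path]:
    """Write one pool's pairs as ``<pool>_1.fastq`` / ``<pool>_2.fastq``.

    Qualities derive from the error model (Q = -10 log10 e); error-free
    simulations write a flat Q40.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    R = batch.read_length
    if error_model is not None:
        quals = error_model.phred_qualities().tolist()
    else:
        quals = [40] * R
    paths = (out_dir / f"{batch.pool_id}_1.fastq", out_dir / f"{batch.pool_id}_2.fastq")
    for mate, path in ((batch.mate1, paths[0]), (batch.mate2, paths[1])):
        records = []
        for i in range(batch.n_pairs):
            rec = SeqRecord(Seq(dna.decode(mate[i])),
                            id=f"{batch.pool_id}:{i}", description="")
            rec.letter_annotations["phred_quality"] = quals
            records.append(rec)
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fastq")
    return paths


def read_fastq_pairs(path1, path2, *, min_mean_quality: float = 0.0,
                     pool_id: str = "") -> ReadBatch:
    """Load a FASTQ pair into a ReadBatch (uniform read length required).

    Pairs whose mean quality (either mate) falls below ``min_mean_quality``
    are dropped.  Malformed records fail with the 1-based record number.
    """
    mats = []
    keep_masks = []
    for path in (path1, path2):
        seqs, keeps = [], []
        n = 0
        with _open(path) as fh:
            try:
                for rec in SeqIO.parse(fh, "fastq"):
                    n += 1
                    seqs.append(dna.encode(str(rec.seq)))
                    q = rec.letter_annotations["phred_quality"]
                    keeps.append(float(np.mean(q)) >= min_mean_quality if q else True)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed FASTQ at record {n + 1}: {exc}") from exc
        if seqs:
            lens = {len(s) for s in seqs}
            if len(lens) != 1:
                raise ValueError(f"{path}: reads must have uniform length, saw {sorted(lens)}")
            mats.append(np.stack(seqs))
        else:
            mats.append(np.empty((0, 0), np.uint8))
        keep_masks.append(np.asarray(keeps, dtype=bool))
    if mats[0].shape[0] != mats[1].shape[0]:
        raise ValueError("mate files differ in record count")
    keep = keep_masks[0] & keep_masks[1] if len(keep_masks[0]) else keep_masks[0]
    m1, m2 = (m[keep] if m.size else m for m in mats)
    n = len(m1)
    z = np.zeros(n, dtype=np.int64)
    return ReadBatch(pool_id or Path(path1).stem.rsplit("_", 1)[0], m1, m2,
                     z.copy(), z.copy(), z.copy(), np.zeros(n, dtype=bool))


# ---------------------------------------------------------------------------
# TSV tables


def write_design_tsv(design, path) -> None:
    rows = [(pid, cid) for pid in sorted(design.membership)
            for cid in sorted(design.membership[pid])]
    pd.DataFrame(rows, columns=["pool_id", "clone_id"]).to_csv(path, sep="\t", index=False)


def read_design_tsv(path, d: int | None = None, p: int | None = None,
                    strategy: str = "declared"):
    from .pooling import PoolDesign

    df = pd.read_csv(path, sep="\t")
    membership: dict[str, set] = {}
    signature: dict[str, list] = {}
    for pid, cid in zip(df.pool_id, df.clone_id):
        membership.setdefault(str(pid), set()).add(str(cid))
        signature.setdefault(str(cid), []).append(str(pid))
    sig = {c: tuple(sorted(v)) for c, v in signature.items()}
    dd = d or len(next(iter(sig.values())))
    if any(len(s) != dd for s in sig.values()):
        raise ValueError("clones are not all in the same number of pools")
    return PoolDesign(dd, p or 0, strategy, membership, sig, sorted(sig))


def write_clones_tsv(clones: list[Clone], path) -> None:
    pd.DataFrame([(c.id, c.chrom, c.start, c.end) for c in clones],
                 columns=["clone_id", "chrom", "start", "end"]).to_csv(
        path, sep="\t", index=False)


def read_clones_tsv(path) -> list[Clone]:
    df = pd.read_csv(path, sep="\t")
    return [Clone(str(r.clone_id), str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples()]


def write_markers_tsv(markers: list[Marker], path) -> None:
    rows = []
    for m in markers:
        if m.clone_hits:
            rows.extend((m.id, m.chrom, m.position, c) for c in sorted(m.clone_hits))
        else:
            rows.append((m.id, m.chrom, m.position, "."))
    pd.DataFrame(rows, columns=["marker_id", "chrom", "position", "clone_id"]).to_csv(
        path, sep="\t", index=False)


def read_markers_tsv(path) -> list[Marker]:
    df = pd.read_csv(path, sep="\t")
    by_id: dict[str, Marker] = {}
    for r in df.itertuples():
        m = by_id.setdefault(str(r.marker_id), Marker(str(r.marker_id), str(r.chrom), int(r.position)))
        if str(r.clone_id) != ".":
            m.clone_hits.add(str(r.clone_id))
    return list(by_id.values())


# ---------------------------------------------------------------------------
# F-set TSV


def write_fset_tsv(fset: FSet, path) -> None:
    """``element<TAB>count`` rows in lexicographic order, with a provenance header."""
    with open(path, "w") as fh:
        fh.write(f"#{fset.kind}/{fset.owner}/{fset.stage}\n")
        fh.write("element\tcount\n")
        for w, c in zip(fset.words, fset.counts):  # numeric order == lexicographic
            fh.write(f"{dna.word_to_string(int(w), fset.klen)}\t{int(c)}\n")


def read_fset_tsv(path) -> FSet:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing #kind/owner/stage header")
        kind, owner, stage = header[1:].split("/")
        df = pd.read_csv(fh, sep="\t")
    if len(df) == 0:
        return FSet(kind, 1, np.empty(0, np.uint64), np.empty(0, np.int64),
                    owner=owner, stage=stage)
    klen = len(str(df.element.iloc[0]))
    words = dna.strings_to_words(df.element.astype(str))
    counts = df["count"].to_numpy(dtype=np.int64)
    order = np.argsort(words)
    return FSet(kind, klen, words[order], counts[order], owner=owner, stage=stage)


# ---------------------------------------------------------------------------
# Contig table and AGP


def write_contig_tsv(contigs: list[PhysContig], singletons: list[str], path) -> None:
    rows = [(c.id, cid, i, int(c.q_flags.get(cid, False)))
            for c in contigs for i, cid in enumerate(c.clones)]
    rows += [("singleton", cid, 0, 0) for cid in sorted(singletons)]
    pd.DataFrame(rows, columns=["contig_id", "clone_id", "position_rank", "q_flag"]).to_csv(
        path, sep="\t", index=False)


def read_contig_tsv(path):
    df = pd.read_csv(path, sep="\t")
    contigs: dict[str, PhysContig] = {}
    singletons: list[str] = []
    for r in df.itertuples():
        if r.contig_id == "singleton":
            singletons.append(str(r.clone_id))
            continue
        c = contigs.setdefault(str(r.contig_id), PhysContig(str(r.contig_id), []))
        c.clones.append(str(r.clone_id))
        c.q_flags[str(r.clone_id)] = bool(r.q_flag)
    return list(contigs.values()), singletons


def write_agp(assembly, path) -> None:
    """AGP v2.1 description of the pseudomolecules (gap type contig/no linkage)."""
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for chrom, pseudo in sorted(assembly.pseudomolecules.items()):
            pos, part = 1, 1
            for i, pl in enumerate(pseudo.placements):
                seq = assembly.scaffolds[pl.contig_id].sequence
                if i > 0:
                    from .anchor import GAP_BETWEEN_CONTIGS
                    gap = GAP_BETWEEN_CONTIGS
                    fh.write(f"{chrom}\t{pos}\t{pos + gap - 1}\t{part}\tN\t{gap}\tcontig\tno\tna\n")
                    pos += gap
                    part += 1
                orient = pl.orientation if pl.orientation in "+-" else "?"
                fh.write(f"{chrom}\t{pos}\t{pos + len(seq) - 1}\t{part}\tW\t"
                         f"{pl.contig_id}\t1\t{len(seq)}\t{orient}\n")
                pos += len(seq)
                part += 1


def write_links_tsv(links: pd.DataFrame, path) -> None:
    links.to_csv(path, sep="\t", index=False)


def read_links_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report_tsv(report, path) -> None:
    pd.DataFrame([vars(report)]).to_csv(path, sep="\t", index=False)
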