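"""Desk-scale read-to-target alignment shared by all profiling stages.

The internal aligner is exact k-mer seeding followed by ungapped extension
along each seeded diagonal (best-scoring segment, +1 match / -2 mismatch).
Raw scores are converted to bit scores and E-values with ungapped
Karlin-Altschul statistics using fixed, documented constants
(lambda = 1.28, K = 0.46, the classical ungapped values for +1/-2 scoring).
It is a contract implementation — "every qualified hit above thresholds" —
not a re-implementation of bowtie2 or DIAMOND; externally produced SAM or
BLAST tabular (m8) hits can be substituted via :func:`read_external_hits`.

Threshold semantics follow the qualified-alignment rule used downstream:
bit score strictly greater than ``min_score`` and E-value strictly less
than ``max_evalue``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .records import AlignmentHit, ReadRecord

__all__ = ["AlignmentIndex", "align_reads", "read_external_hits", "six_frame_translate"]

# Ungapped Karlin-Altschul constants for +1/-2 match/mismatch scoring.
KA_LAMBDA = 1.28
KA_K = 0.46
MATCH = 1
MISMATCH = -2
XDROP = 20

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def six_frame_translate(seq: str) -> list[str]:
    """All six conceptual translations of a DNA sequence (stops kept as ``*``)."""
    frames = []
    for s in (seq, revcomp(seq)):
        for off in range(3):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            frames.append(str(Seq(sub).translate()))
    return frames


class AlignmentIndex:
    """Exact k-mer index over a set of target sequences.

    Parameters
    ----------
    targets : mapping of target id to sequence
    alphabet : ``dna`` or ``protein``; protein indexes expect amino-acid
        target sequences and six-frame-translate DNA reads before seeding.
    k : seed length; defaults to 21 for DNA and 5 for protein.
    target_kind : label stamped onto emitted hits.
    """

    def __init__(self, targets: dict[str, str], alphabet: str = "dna",
                 k: int | None = None, target_kind: str = "genome"):
        if not targets:
            raise ValueError("empty alignment index")
        if alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {alphabet!r}")
        self.alphabet = alphabet
        self.k = k if k is not None else (21 if alphabet == "dna" else 5)
        self.target_kind = target_kind
        self.target_ids = sorted(targets)
        self.target_seqs = [targets[t] for t in self.target_ids]
        self.db_size = sum(len(s) for s in self.target_seqs)
        self._index: dict[str, list[tuple[int, int]]] = {}
        k_ = self.k
        for ti, seq in enumerate(self.target_seqs):
            idx = self._index
            for pos in range(len(seq) - k_ + 1):
                kmer = seq[pos : pos + k_]
                if kmer in idx:
                    idx[kmer].append((ti, pos))
                else:
                    idx[kmer] = [(ti, pos)]

    # ------------------------------------------------------------------ core

    def _extend(self, query: str, ti: int, diag: int) -> tuple[int, float] | None:
        """Best ungapped segment of query vs target along one diagonal.

        ``diag`` is target_pos - query_pos. Returns (raw_score, identity)
        of the maximal-scoring segment, or None when the overlap is empty.
        """
        target = self.target_seqs[ti]
        qstart = max(0, -diag)
        qend = min(len(query), len(target) - diag)
        if qend <= qstart:
            return None
        # Kadane over per-position +1/-2 scores, tracking identity of the
        # best segment.
        best = 0
        best_len = 0
        best_matches = 0
        cur = 0
        cur_start = qstart
        cur_matches = 0
        for q in range(qstart, qend):
            s = MATCH if query[q] == target[q + diag] else MISMATCH
            if cur <= 0:
                cur = 0
                cur_start = q
                cur_matches = 0
            cur += s
            if s > 0:
                cur_matches += 1
            if cur > best:
                best = cur
                best_len = q - cur_start + 1
                best_matches = cur_matches
        if best <= 0:
            return None
        return best, best_matches / best_len

    def _query_hits(self, query: str) -> dict[int, tuple[int, float]]:
        """Best raw score and identity per target for one query string."""
        k = self.k
        idx = self._index
        seen: set[tuple[int, int]] = set()
        best: dict[int, tuple[int, float]] = {}
        for qpos in range(len(query) - k + 1):
            entries = idx.get(query[qpos : qpos + k])
            if not entries:
                continue
            for ti, tpos in entries:
                key = (ti, tpos - qpos)
                if key in seen:
                    continue
                seen.add(key)
                ext = self._extend(query, ti, key[1])
                if ext is None:
                    continue
                if ti not in best or ext[0] > best[ti][0]:
                    best[ti] = ext
        return best

    def bit_score(self, raw: int) -> float:
        return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2)

    def evalue(self, bit: float, query_len: int) -> float:
        return query_len * self.db_size * 2.0 ** (-bit)


def align_reads(reads: Sequence[ReadRecord], index: AlignmentIndex,
                mode: str = "all_hits", min_score: float = 0.0,
                max_evalue: float = 1e-5,
                min_identity: float = 0.0) -> list[AlignmentHit]:
    """Align reads against an index, returning every qualified hit.

    ``all_hits`` returns every hit passing the thresholds (the ``-a``
    contract); ``best_hit`` keeps only the top-scoring hit per read
    (ties broken by target id). Protein indexes six-frame-translate each
    DNA read before seeding and keep the best frame per target.
    """
    if mode not in ("all_hits", "best_hit"):
        raise ValueError(f"unknown mode {mode!r}")
    hits: list[AlignmentHit] = []
    for read in reads:
        if index.alphabet == "dna":
            # search both strands, keep the best per target
            per_target = index._query_hits(read.sequence)
            for ti, ext in index._query_hits(revcomp(read.sequence)).items():
                if ti not in per_target or ext[0] > per_target[ti][0]:
                    per_target[ti] = ext
            qlen = len(read.sequence)
        else:
            per_target: dict[int, tuple[int, float]] = {}
            qlen = max(1, len(read.sequence) // 3)
            for frame in six_frame_translate(read.sequence):
                for ti, ext in index._query_hits(frame).items():
                    if ti not in per_target or ext[0] > per_target[ti][0]:
                        per_target[ti] = ext
        read_hits = []
        for ti, (raw, ident) in per_target.items():
            bit = index.bit_score(raw)
            ev = index.evalue(bit, qlen)
            if bit > min_score and ev < max_evalue and ident >= min_identity:
                read_hits.append(
                    AlignmentHit(read.read_id, index.target_ids[ti], bit, ev,
                                 ident, index.target_kind)
                )
        if mode == "best_hit" and read_hits:
            read_hits = [min(read_hits, key=lambda h: (-h.score, h.target_id))]
        hits.extend(sorted(read_hits, key=lambda h: h.target_id))
    return hits


# ------------------------------------------------------------ external hits


def read_external_hits(path, format: str, target_kind: str = "genome",
                       min_score: float = float("-inf"),
                       max_evalue: float = float("inf")) -> list[AlignmentHit]:
    """Normalize externally produced alignments to :class:`AlignmentHit`.

    ``blast_m8`` is 12-column BLAST/DIAMOND tabular (column 11 E-value,
    column 12 bit score). ``sam`` accepts plain-text SAM; the score is the
    ``AS`` tag when present, identity is derived from the ``NM`` tag, and
    the E-value defaults to 0 (SAM carries none). Unmapped records are
    skipped. Threshold semantics are strict, matching the internal aligner.
    """
    hits: list[AlignmentHit] = []
    if format == "blast_m8":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 12:
                    raise ValueError(f"{path}:{lineno}: expected 12 m8 columns")
                try:
                    ident = float(fields[2]) / 100.0
                    ev = float(fields[10])
                    bit = float(fields[11])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                if bit > min_score and ev < max_evalue:
                    hits.append(AlignmentHit(fields[0], fields[1], bit, ev,
                                             ident, target_kind))
    elif format == "sam":
        import pysam

        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped:
                    continue
                score = float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0
                alen = rec.query_alignment_length or len(rec.query_sequence or "")
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                ident = max(0.0, 1.0 - nm / alen) if alen else 0.0
                if score > min_score:
                    hits.append(AlignmentHit(rec.query_name, rec.reference_name,
                                             score, 0.0, ident, target_kind))
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    return hits


def write_hits_tsv(path, hits: Iterable[AlignmentHit]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttarget_id\ttarget_kind\tscore\tevalue\tidentity\n")
        for h in hits:
            fh.write(f"{h.read_id}\t{h.target_id}\t{h.target_kind}"
                     f"\t{h.score:.3f}\t{h.evalue:.3g}\t{h.identity:.4f}\n")
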