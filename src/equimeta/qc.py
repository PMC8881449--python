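"""Five-rule read quality control with pair-aware discarding.

A read is discarded when it (1) contains two or more ambiguous (N) bases,
(2) contains 30 or more bases below Q20, (3) matches the adapter, or
(4) aligns to the host/plant reference; up to 29 sub-Q20 bases are first
trimmed from the 3' end (rule 5), and rules 1-4 are evaluated on the
trimmed read. Adapter and host discards also remove the mate; a mate
orphaned by an ambiguous/low-quality discard is routed to a singleton
stream and excluded from paired profiling.

Adapter detection mimics the effect of cutadapt with ``-u 6``: the first
six bases are clipped from the candidate read, then the adapter is sought
as an internal match or a 3'-suffix overlap (at most 10% mismatches). The
default minimum overlap is 16: on random 150-mers, shorter overlaps
produce chance matches at a rate incompatible with label-exact filtering
of defect-free reads (about 6e-5 per read at overlap 8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .align import AlignmentIndex, align_reads
from .records import ReadPair, ReadRecord

__all__ = ["QCParams", "QCResult", "trim_3prime_lowq", "matches_adapter",
           "filter_pair", "run_qc", "build_host_index"]


def build_host_index(host_sequences: dict[str, str], k: int = 25) -> AlignmentIndex:
    """Index the host/plant reference(s) for the rule-4 removal step."""
    return AlignmentIndex(host_sequences, alphabet="dna", k=k, target_kind="host")


@dataclass
class QCParams:
    q_threshold: int = 20          # Phred cutoff defining a low-quality base
    max_lowq: int = 30             # rule 2: discard at >= this many sub-Q20 bases
    max_ambiguous: int = 2         # rule 1: discard at >= this many N bases
    max_trim: int = 29             # rule 5: 3' trim cap
    adapter_min_overlap: int = 16
    adapter_max_mismatch_frac: float = 0.10
    adapter_clip_first: int = 6    # the -u 6 effect, applied before matching
    host_min_identity: float = 0.9
    host_max_evalue: float = 1e-5
    host_seed_k: int = 25          # long seed keeps chance host hits ~0


@dataclass
class QCResult:
    kept_pairs: list[ReadPair]
    singletons: list[ReadRecord]
    report: pd.DataFrame  # read_id, mate, decision, stream, trimmed_bases


def trim_3prime_lowq(read: ReadRecord, max_trim: int = 29,
                     q_threshold: int = 20) -> ReadRecord:
    """Trim the trailing run of sub-threshold bases, capped at ``max_trim``.

    Never discards: a longer run is trimmed only up to the cap and the
    remaining low-quality bases are left for rule 2 to count.
    """
    run = 0
    for q in reversed(read.qualities):
        if q < q_threshold:
            run += 1
        else:
            break
    n = min(run, max_trim)
    if n == 0:
        return read
    return ReadRecord(read.read_id, read.sequence[:-n], read.qualities[:-n], read.mate)


def matches_adapter(sequence: str, adapter: str, min_overlap: int = 8,
                    max_mismatch_frac: float = 0.10, clip_first: int = 6) -> bool:
    """True when the adapter occurs internally or as a 3'-suffix overlap."""
    seq = sequence[clip_first:]
    if not adapter or len(seq) < min_overlap:
        return False
    for start in range(len(seq) - min_overlap + 1):
        overlap = min(len(adapter), len(seq) - start)
        window = seq[start : start + overlap]
        mism = sum(a != b for a, b in zip(window, adapter))
        if mism <= max_mismatch_frac * overlap:
            return True
    return False


def _read_status(read: ReadRecord, adapter: str | None,
                 host_index: AlignmentIndex | None, params: QCParams) -> str:
    if read.sequence.count("N") >= params.max_ambiguous:
        return "ambiguous"
    if sum(q < params.q_threshold for q in read.qualities) >= params.max_lowq:
        return "lowq"
    if adapter and matches_adapter(read.sequence, adapter,
                                   params.adapter_min_overlap,
                                   params.adapter_max_mismatch_frac,
                                   params.adapter_clip_first):
        return "adapter"
    if host_index is not None and align_reads(
        [read], host_index, max_evalue=params.host_max_evalue,
        min_identity=params.host_min_identity,
    ):
        return "host"
    return "kept"


def filter_pair(pair: ReadPair, adapter: str | None = None,
                host_index: AlignmentIndex | None = None,
                params: QCParams | None = None,
                ) -> tuple[ReadPair | None, ReadRecord | None, list[dict]]:
    """Apply trim-then-filter to one pair.

    Returns (kept pair or None, orphaned singleton or None, per-read report
    rows). Adapter/host failures co-discard the mate (``discarded_mate``);
    ambiguous/low-quality failures orphan it into the singleton stream.
    """
    params = params or QCParams()
    trimmed = {}
    trim_counts = {}
    for read in (pair.r1, pair.r2):
        t = trim_3prime_lowq(read, params.max_trim, params.q_threshold)
        trimmed[read.mate] = t
        trim_counts[read.mate] = len(read) - len(t)
    status = {m: _read_status(trimmed[m], adapter, host_index, params)
              for m in ("R1", "R2")}

    decision = {}
    if "adapter" in status.values() or "host" in status.values():
        for m in ("R1", "R2"):
            if status[m] in ("adapter", "host"):
                decision[m] = ("discarded_" + status[m], "none")
            elif status[m] in ("ambiguous", "lowq"):
                decision[m] = ("discarded_" + status[m], "none")
            else:
                decision[m] = ("discarded_mate", "none")
        kept, singleton = None, None
    else:
        for m in ("R1", "R2"):
            if status[m] in ("ambiguous", "lowq"):
                decision[m] = ("discarded_" + status[m], "none")
            else:
                decision[m] = ("kept", "paired")
        kept = singleton = None
        if decision["R1"][0] == "kept" and decision["R2"][0] == "kept":
            kept = ReadPair(trimmed["R1"], trimmed["R2"])
        elif decision["R1"][0] == "kept":
            decision["R1"] = ("kept", "singleton")
            singleton = trimmed["R1"]
        elif decision["R2"][0] == "kept":
            decision["R2"] = ("kept", "singleton")
            singleton = trimmed["R2"]

    rows = [
        {"read_id": pair.pair_id, "mate": m, "decision": decision[m][0],
         "stream": decision[m][1], "trimmed_bases": trim_counts[m]}
        for m in ("R1", "R2")
    ]
    return kept, singleton, rows


def run_qc(pairs: list[ReadPair], adapter: str | None = None,
           host_index: AlignmentIndex | None = None,
           params: QCParams | None = None) -> QCResult:
    """QC a collection of pairs, producing kept/singleton streams + report."""
    params = params or QCParams()
    kept_pairs: list[ReadPair] = []
    singletons: list[ReadRecord] = []
    rows: list[dict] = []
    for pair in pairs:
        kept, single, pair_rows = filter_pair(pair, adapter, host_index, params)
        if kept is not None:
            kept_pairs.append(kept)
        if single is not None:
            singletons.append(single)
        rows.extend(pair_rows)
    return QCResult(kept_pairs, singletons, pd.DataFrame(rows))
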