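"""Independent brute-force pileup oracle.

Counts methylated/unmethylated calls per reference cytosine with a plain
Python dict, walking each read's aligned pairs one base at a time.  This
deliberately shares no traversal code with the package's vectorised
accumulator: pysam's ``get_aligned_pairs`` supplies (query, reference)
coordinate pairs, contexts are looked up directly in the reference string,
and counts live in a dictionary keyed by (chrom, pos, strand).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pysam

from methdomains.calling import trim_read


def bruteforce_pileup(
    sam_path: str,
    reference: Mapping[str, str],
    trim: bool = True,
    max_length: Optional[int] = 80,
    min_quality: int = 30,
) -> Dict[Tuple[str, int, str], Tuple[int, int]]:
    """(chrom, pos0, strand) -> (n_meth, n_total) over CG and CH cytosines.

    Only gapless single-block alignments are trimmed, matching the caller's
    documented behaviour; gapped reads are counted untrimmed.
    """
    counts: Dict[Tuple[str, int, str], list] = defaultdict(lambda: [0, 0])
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            chrom = read.reference_name
            if chrom not in reference:
                continue
            ref = reference[chrom]
            if read.has_tag("ZS"):
                is_ot = str(read.get_tag("ZS")).startswith("+")
            elif read.has_tag("XG"):
                is_ot = str(read.get_tag("XG")) == "CT"
            else:
                is_ot = not read.is_reverse
            seq = read.query_sequence
            quals = read.query_qualities
            cigar = read.cigartuples or [(0, len(seq))]
            simple = len(cigar) == 1 and cigar[0][0] in (0, 7, 8)
            if trim and simple:
                trimmed = trim_read(
                    np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy(),
                    np.asarray(quals, dtype=np.int16) if quals is not None else None,
                    read.reference_start,
                    read.is_reverse,
                    max_length,
                    min_quality,
                )
                if trimmed is None:
                    continue
                codes, _, start = trimmed
                pairs = [(q, start + q) for q in range(len(codes))]
                seq = codes.tobytes().decode()
            else:
                pairs = [
                    (q, r)
                    for q, r in read.get_aligned_pairs(matches_only=True)
                    if q is not None and r is not None
                ]
            for qpos, rpos in pairs:
                base = seq[qpos].upper()
                refbase = ref[rpos].upper()
                if is_ot and refbase == "C":
                    key = (chrom, rpos, "+")
                    if base == "C":
                        counts[key][0] += 1
                        counts[key][1] += 1
                    elif base == "T":
                        counts[key][1] += 1
                elif (not is_ot) and refbase == "G":
                    key = (chrom, rpos, "-")
                    if base == "G":
                        counts[key][0] += 1
                        counts[key][1] += 1
                    elif base == "A":
                        counts[key][1] += 1
    return {k: (v[0], v[1]) for k, v in counts.items() if v[1] > 0}


def bruteforce_conversion(
    sam_path: str,
    reference: Mapping[str, str],
    trim: bool = True,
    max_length: Optional[int] = 80,
    min_quality: int = 30,
) -> Tuple[int, int]:
    """(C calls, all base calls) at non-CpG cytosines, strand-aware.

    Unlike the pileup above this also counts non-C/T (mismatch) base calls
    in the denominator, mirroring 'all bases at non-CpG positions'.
    """
    n_c = 0
    n_all = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            chrom = read.reference_name
            if chrom not in reference:
                continue
            ref = reference[chrom]
            if read.has_tag("ZS"):
                is_ot = str(read.get_tag("ZS")).startswith("+")
            else:
                is_ot = not read.is_reverse
            seq = read.query_sequence
            quals = read.query_qualities
            cigar = read.cigartuples or [(0, len(seq))]
            simple = len(cigar) == 1 and cigar[0][0] in (0, 7, 8)
            if trim and simple:
                trimmed = trim_read(
                    np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy(),
                    np.asarray(quals, dtype=np.int16) if quals is not None else None,
                    read.reference_start,
                    read.is_reverse,
                    max_length,
                    min_quality,
                )
                if trimmed is None:
                    continue
                codes, _, start = trimmed
                pairs = [(q, start + q) for q in range(len(codes))]
                seq = codes.tobytes().decode()
            else:
                pairs = [
                    (q, r)
                    for q, r in read.get_aligned_pairs(matches_only=True)
                    if q is not None and r is not None
                ]
            for qpos, rpos in pairs:
                refbase = ref[rpos].upper()
                if is_ot and refbase == "C":
                    nxt = ref[rpos + 1].upper() if rpos + 1 < len(ref) else ""
                    if nxt != "G":  # non-CpG cytosine, top strand
                        n_all += 1
                        if seq[qpos].upper() == "C":
                            n_c += 1
                elif (not is_ot) and refbase == "G":
                    prv = ref[rpos - 1].upper() if rpos > 0 else ""
                    if prv != "C":  # non-CpG cytosine, bottom strand
                        n_all += 1
                        if seq[qpos].upper() == "G":
                            n_c += 1
    return n_c, n_all
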