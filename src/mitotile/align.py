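"""Read alignment to the circular reference and read-level filtering.

Alignment is seed-and-extend: read k-mers are looked up in an index built
over the *doubled* reference sequence (so reads spanning the origin align
contiguously), then the read is fit against a reference window with a banded
affine-gap dynamic program (match +1, mismatch -4, gap open -6 for the first
gap base, -1 per extension, band 16).  The fit is semi-global: the read is
consumed end to end, reference flanks are free.  A full-matrix version of
the same DP (``band=None``) serves as an exact oracle.

After alignment the filters mirror a forensic amplicon pipeline:

* per-base quality masking (Q < 30 excluded from pileups, strictly),
* short-byproduct removal (pairs with inferred insert < 40 nt discarded),
* primer trimming (bases over the assigned amplicon's primer footprints are
  soft-clipped so only insert sequence is counted),
* nuclear-insert (NUMT) exclusion by nearest-reference classification
  against a decoy set,
* reverse-strand soft-clipping across the HVII C-stretch, where reverse
  reads lose alignment fidelity: affected reads contribute no counts past
  position 303.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import edlib
from Bio import SeqIO

from .panel import Panel
from .reference import CircularGenome, Region
from .simulate import revcomp


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -4
    gap_open: int = -6  # cost of the first base of a gap
    gap_extend: int = -1
    band: int = 16


DEFAULT_SCORING = Scoring()
_NEG = -(10**9)


def fit_align(
    query: str,
    ref: str,
    band: Optional[int] = None,
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[int, int, list[tuple[str, int]]]:
    """Fitting alignment of ``query`` against ``ref`` (affine gaps).

    The query is aligned end to end; leading and trailing reference bases are
    free.  ``band=None`` computes the full matrix (exact); an integer band
    restricts the DP to a diagonal corridor of half-width ``band`` centred on
    the expected diagonal.

    Returns ``(score, ref_start_offset, cigar)`` where cigar ops are ``M``
    (match/mismatch), ``I`` (read base absent from reference) and ``D``
    (reference base absent from read), consuming the query exactly.
    """
    n, m = len(query), len(ref)
    if n == 0:
        return 0, 0, []
    ma, mi = scoring.match, scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend
    if band is None:
        jlo = [0] * (n + 1)
        jhi = [m] * (n + 1)
    else:
        off = (m - n) // 2
        jlo = [max(0, i + off - band) for i in range(n + 1)]
        jhi = [min(m, i + off + band) for i in range(n + 1)]

    # rows indexed by j - jlo[i]; pointers: 0 diag, 1 up/E, 2 left/F, 3 start
    H_prev = [0] * (jhi[0] - jlo[0] + 1)
    E_prev = [_NEG] * len(H_prev)
    PH: list[list[int]] = [[3] * len(H_prev)]
    PE: list[list[int]] = [[0] * len(H_prev)]
    PF: list[list[int]] = [[0] * len(H_prev)]
    for i in range(1, n + 1):
        lo, hi = jlo[i], jhi[i]
        width = hi - lo + 1
        H_cur = [_NEG] * width
        E_cur = [_NEG] * width
        ph_row = [0] * width
        pe_row = [0] * width
        pf_row = [0] * width
        plo, phi = jlo[i - 1], jhi[i - 1]
        qc = query[i - 1]
        F = _NEG
        f_ext = 0
        for idx in range(width):
            j = lo + idx
            # E: gap in reference (read insertion), vertical move
            e = _NEG
            pe = 0
            if plo <= j <= phi:
                up_h = H_prev[j - plo]
                up_e = E_prev[j - plo]
                open_sc = up_h + go
                ext_sc = up_e + ge
                if ext_sc > open_sc:
                    e, pe = ext_sc, 1
                else:
                    e, pe = open_sc, 0
            # F: gap in read (reference deletion), horizontal move
            if j > lo:
                left_h = H_cur[idx - 1]
                open_sc = left_h + go
                ext_sc = F + ge
                if ext_sc > open_sc:
                    F, f_ext = ext_sc, 1
                else:
                    F, f_ext = open_sc, 0
            else:
                F, f_ext = _NEG, 0
            # H: best of diagonal, E, F
            best = _NEG
            pb = 0
            if j >= 1 and plo <= j - 1 <= phi:
                diag = H_prev[j - 1 - plo] + (ma if ref[j - 1] == qc else mi)
                if diag > best:
                    best, pb = diag, 0
            if e > best:
                best, pb = e, 1
            if F > best:
                best, pb = F, 2
            H_cur[idx] = best
            E_cur[idx] = e
            ph_row[idx] = pb
            pe_row[idx] = pe
            pf_row[idx] = f_ext
        H_prev, E_prev = H_cur, E_cur
        PH.append(ph_row)
        PE.append(pe_row)
        PF.append(pf_row)

    # best end position in the last row (trailing reference is free)
    best_idx = max(range(len(H_prev)), key=lambda k: H_prev[k])
    score = H_prev[best_idx]
    # traceback
    ops: list[str] = []
    i, j = n, jlo[n] + best_idx
    state = "H"
    while i > 0:
        idx = j - jlo[i]
        if state == "H":
            p = PH[i][idx]
            if p == 0:
                ops.append("M")
                i -= 1
                j -= 1
            elif p == 1:
                state = "E"
            elif p == 2:
                state = "F"
            else:  # start cell inside row > 0 cannot happen
                break
        elif state == "E":
            ops.append("I")
            nxt = PE[i][idx]
            i -= 1
            state = "E" if nxt else "H"
        else:  # F
            ops.append("D")
            nxt = PF[i][idx]
            j -= 1
            state = "F" if nxt else "H"
    ref_start = j
    # aggregate ops
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return score, ref_start, cigar


@dataclass
class AlignedRead:
    """One aligned mate in aligned orientation (sequence/qualities are
    reverse-complemented for reverse-strand alignments, so query offsets run
    along ascending reference positions)."""

    read_id: str
    seq: str
    qual: str
    strand: str  # "+" | "-"
    ref_start: int  # 1-based circular coordinate of first aligned ref base
    linear_start: int  # 0-based offset on the doubled sequence (pair geometry)
    cigar: list[tuple[str, int]]
    score: int
    aligned: bool = True
    amplicon_id: Optional[str] = None
    masked_offsets: set[int] = field(default_factory=set)  # Q<30 query offsets
    clipped_offsets: set[int] = field(default_factory=set)  # primer/HVII clips
    excluded_ref: set[int] = field(default_factory=set)  # ref pos clipped out
    flags: dict = field(default_factory=dict)

    def walk(self, genome_length: int):
        """Yield alignment columns: ``('M', ref_pos, query_offset)``,
        ``('D', ref_pos, None)`` and ``('I', anchor_ref_pos, (offset, length))``."""
        qoff = 0
        lin = self.linear_start
        for op, length in self.cigar:
            if op == "M":
                for _ in range(length):
                    yield "M", lin % genome_length + 1, qoff
                    qoff += 1
                    lin += 1
            elif op == "D":
                for _ in range(length):
                    yield "D", lin % genome_length + 1, None
                    lin += 1
            elif op == "I":
                anchor = (lin - 1) % genome_length + 1
                yield "I", anchor, (qoff, length)
                qoff += length
            elif op == "S":
                qoff += length

    def ref_span_linear(self) -> tuple[int, int]:
        consumed = sum(l for op, l in self.cigar if op in ("M", "D"))
        return self.linear_start, self.linear_start + consumed - 1


class CircularIndex:
    """k-mer index over the doubled reference for circular seeding."""

    def __init__(self, genome: CircularGenome, k: int = 15, max_hits: int = 64):
        self.genome = genome
        self.k = k
        self.doubled = genome.sequence * 2
        self.kmers: dict[str, list[int]] = {}
        for i in range(len(self.doubled) - k + 1):
            kmer = self.doubled[i : i + k]
            hits = self.kmers.setdefault(kmer, [])
            if len(hits) < max_hits:
                hits.append(i)

    def candidates(self, seq: str, n_seeds: int = 4) -> list[int]:
        """Candidate 0-based start diagonals (normalized to [0, L))."""
        n, k, L = len(seq), self.k, self.genome.length
        if n < k:
            return []
        offsets = sorted({0, n // 3, (2 * n) // 3, n - k}) if n_seeds >= 4 else [0]
        diags: dict[int, int] = {}
        for off in offsets:
            for pos in self.kmers.get(seq[off : off + k], []):
                d = (pos - off) % L
                diags[d] = diags.get(d, 0) + 1
        merged: dict[int, int] = {}
        for d, cnt in sorted(diags.items()):
            for d0 in merged:
                if abs(d - d0) <= 8 or abs(d - d0) >= L - 8:
                    merged[d0] += cnt
                    break
            else:
                merged[d] = cnt
        return [d for d, _ in sorted(merged.items(), key=lambda kv: -kv[1])[:3]]


def _hamming_score(a: str, b: str, scoring: Scoring) -> tuple[int, int]:
    mm = sum(1 for x, y in zip(a, b) if x != y)
    return (len(a) - mm) * scoring.match + mm * scoring.mismatch, mm


def _single_indel_path(
    query: str, doubled: str, cand: int, scoring: Scoring, max_indel: int = 8
) -> Optional[tuple[int, int, list[tuple[str, int]]]]:
    """Exact fast path for reads carrying one clean indel: an error-free
    prefix on the candidate diagonal plus an error-free suffix on a diagonal
    shifted by the indel length.  Returns (score, linear_start, cigar) or
    None; mismatch-carrying indel reads fall through to the banded DP."""
    n = len(query)
    w0 = doubled[cand : cand + n]
    if len(w0) < n:
        return None
    p = 0
    while p < n and query[p] == w0[p]:
        p += 1
    if p == n:
        return None  # exact; the caller's Hamming path already handles this
    for d in range(1, max_indel + 1):
        # read insertion of length d: suffix aligns at diagonal -d
        if cand + n - d <= len(doubled) and n - d > p - 1 and cand - d >= 0:
            m = n
            while m > 0 and m - 1 - d >= 0 and query[m - 1] == doubled[cand + m - 1 - d]:
                m -= 1
            k = p  # insertion starts at first mismatch
            if m - d <= k <= n - d:
                score = (n - d) * scoring.match + scoring.gap_open + (d - 1) * scoring.gap_extend
                cigar = [("M", k), ("I", d), ("M", n - k - d)]
                return score, cand, [c for c in cigar if c[1] > 0]
        # reference deletion of length d: suffix aligns at diagonal +d
        if cand + n + d <= len(doubled):
            m = n
            while m > 0 and query[m - 1] == doubled[cand + m - 1 + d]:
                m -= 1
            k = p
            if m <= k <= n:
                score = n * scoring.match + scoring.gap_open + (d - 1) * scoring.gap_extend
                cigar = [("M", k), ("D", d), ("M", n - k)]
                return score, cand, [c for c in cigar if c[1] > 0]
    return None


def align_read(
    read_id: str,
    seq: str,
    qual: str,
    index: CircularIndex,
    panel: Optional[Panel] = None,
    scoring: Scoring = DEFAULT_SCORING,
    min_score_frac: float = 0.33,
) -> AlignedRead:
    """Align one mate to the circular reference, trying both orientations.

    Error-free and substitution-only reads take an O(n) comparison fast path;
    the banded DP runs only when the seeded window disagrees by more than two
    mismatches (possible indel).  Unalignable reads are returned flagged
    rather than raising.
    """
    L = index.genome.length
    best = None  # (score, strand, linear_start, cigar, oriented_seq, oriented_qual)
    for strand, oriented, oqual in (("+", seq, qual), ("-", revcomp(seq), qual[::-1])):
        for cand in index.candidates(oriented):
            n = len(oriented)
            window = index.doubled[cand : cand + n]
            if len(window) == n:
                score, mm = _hamming_score(oriented, window, scoring)
                if mm <= 2:
                    if best is None or score > best[0]:
                        best = (score, strand, cand, [("M", n)], oriented, oqual)
                    continue
                hit = _single_indel_path(oriented, index.doubled, cand, scoring)
                if hit is not None:
                    score, lin, cigar = hit
                    if best is None or score > best[0]:
                        best = (score, strand, lin, cigar, oriented, oqual)
                    continue
            pad = scoring.band // 2
            wstart = max(0, cand - pad)
            window = index.doubled[wstart : cand + n + pad]
            score, roff, cigar = fit_align(oriented, window, scoring.band, scoring)
            if best is None or score > best[0]:
                best = (score, strand, wstart + roff, cigar, oriented, oqual)
    min_score = int(min_score_frac * len(seq) * scoring.match)
    if best is None or best[0] < min_score:
        ar = AlignedRead(
            read_id=read_id,
            seq=seq,
            qual=qual,
            strand="+",
            ref_start=1,
            linear_start=0,
            cigar=[],
            score=best[0] if best else _NEG,
            aligned=False,
        )
        ar.flags["unaligned"] = True
        return ar
    score, strand, lin, cigar, oriented, oqual = best
    ar = AlignedRead(
        read_id=read_id,
        seq=oriented,
        qual=oqual,
        strand=strand,
        ref_start=lin % L + 1,
        linear_start=lin,
        cigar=cigar,
        score=score,
    )
    _right_normalize_insertions(ar, index.doubled)
    if panel is not None:
        ar.amplicon_id = assign_amplicon(ar, panel, L)
    return ar


def _right_normalize_insertions(ar: AlignedRead, doubled: str) -> None:
    """Shift insertions as far 3' along the read as the reference allows.

    Score-equivalent placements of an insertion next to a matching reference
    base are resolved to the rightmost one, matching the forensic convention
    of anchoring insertions at the 3' end of a repeated motif.  Without this,
    a left-aligned placement can land inside a primer footprint and lose the
    insertion evidence for one of two overlapping amplicons.
    """
    out: list[tuple[str, int]] = []
    qoff = 0
    lin = ar.linear_start
    changed = False

    def push(op: str, length: int) -> None:
        if length <= 0:
            return
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + length)
        else:
            out.append((op, length))

    for i, (op, length) in enumerate(ar.cigar):
        if op == "M":
            push("M", length)
            qoff += length
            lin += length
        elif op == "D":
            push("D", length)
            lin += length
        elif op == "S":
            push("S", length)
            qoff += length
        else:  # I: shift right while the read matches the upcoming reference
            follow = (
                ar.cigar[i + 1][1]
                if i + 1 < len(ar.cigar) and ar.cigar[i + 1][0] == "M"
                else 0
            )
            shift = 0
            while (
                shift < follow
                and lin + shift < len(doubled)
                and ar.seq[qoff + shift] == doubled[lin + shift]
            ):
                shift += 1
            if shift:
                changed = True
                push("M", shift)
                # consume the shift from the following M run
                nxt = ar.cigar[i + 1]
                ar.cigar[i + 1] = (nxt[0], nxt[1] - shift)
            push("I", length)
            qoff += length + shift
            lin += shift
    if changed:
        ar.cigar = [c for c in out if c[1] > 0]


_panel_interval_cache: dict[int, list[tuple[str, int, int]]] = {}


def _amplicon_intervals(panel: Panel, genome_length: int) -> list[tuple[str, int, int]]:
    """Per amplicon: (id, linear outer start in [0, L), outer length)."""
    key = id(panel)
    cached = _panel_interval_cache.get(key)
    if cached is None:
        from .reference import region_length

        cached = [
            (a.id, a.outer.start - 1, region_length(a.outer, genome_length))
            for a in panel.amplicons
        ]
        _panel_interval_cache[key] = cached
    return cached


def assign_amplicon(ar: AlignedRead, panel: Panel, genome_length: int) -> Optional[str]:
    """The amplicon whose outer span best contains the alignment (maximum
    overlap; ties go to the shorter amplicon)."""
    s, e = ar.ref_span_linear()
    best_id, best_key = None, None
    for amp_id, o_start, o_len in _amplicon_intervals(panel, genome_length):
        ov = 0
        for base in (o_start, o_start + genome_length, o_start + 2 * genome_length):
            lo = max(s, base)
            hi = min(e, base + o_len - 1)
            if hi >= lo:
                ov = max(ov, hi - lo + 1)
        if ov == 0:
            continue
        key = (ov, -o_len)
        if best_key is None or key > best_key:
            best_key, best_id = key, amp_id
    return best_id


def mask_low_quality(ar: AlignedRead, min_q: int = 30) -> set[int]:
    """Mask query offsets whose Phred quality is strictly below ``min_q``.

    Masking excludes the base call from pileup counting without disturbing
    the alignment anchoring.
    """
    if len(ar.qual) != len(ar.seq):
        raise ValueError("quality string length != sequence length")
    masked = {i for i, c in enumerate(ar.qual) if ord(c) - 33 < min_q}
    ar.masked_offsets |= masked
    return masked


def pair_insert_length(a: AlignedRead, b: AlignedRead, genome_length: int) -> Optional[int]:
    """Template length inferred from the two mates' aligned spans (circular)."""
    if not (a.aligned and b.aligned):
        return None
    s1, e1 = a.ref_span_linear()
    s2, e2 = b.ref_span_linear()
    # normalize mates onto the same copy of the doubled sequence
    if s2 - s1 > genome_length // 2:
        s2 -= genome_length
        e2 -= genome_length
    elif s1 - s2 > genome_length // 2:
        s1 -= genome_length
        e1 -= genome_length
    return max(e1, e2) - min(s1, s2) + 1


def filter_byproduct(
    a: AlignedRead, b: AlignedRead, genome_length: int, min_insert: int = 40
) -> bool:
    """Keep a pair iff its inferred insert length is >= ``min_insert`` (short
    primer/adapter byproducts are discarded; 40 kept, 39 discarded)."""
    tlen = pair_insert_length(a, b, genome_length)
    if tlen is None:
        return True  # cannot infer; unaligned mates are dropped elsewhere
    kept = tlen >= min_insert
    if not kept:
        a.flags["byproduct_filtered"] = True
        b.flags["byproduct_filtered"] = True
    return kept


def trim_primers(ar: AlignedRead, panel: Panel, genome_length: int) -> AlignedRead:
    """Soft-clip read bases that fall on the assigned amplicon's primer
    footprints so only insert bases reach the pileup."""
    if ar.amplicon_id is None:
        ar.flags["untrimmed"] = True
        return ar
    L = genome_length
    # footprints as linear 0-based intervals, replicated across the doubled
    # coordinate space so cigar runs can be clipped with interval arithmetic
    spans: list[tuple[int, int]] = []
    for r in panel.primer_regions(ar.amplicon_id, L):
        s0 = r.start - 1
        ln = (r.end - r.start) % L + 1
        for base in (s0, s0 + L, s0 + 2 * L):
            spans.append((base, base + ln - 1))
    qoff = 0
    lin = ar.linear_start
    for op, length in ar.cigar:
        if op == "M":
            run_end = lin + length - 1
            for lo_s, hi_s in spans:
                lo = max(lin, lo_s)
                hi = min(run_end, hi_s)
                if hi >= lo:
                    ar.clipped_offsets.update(
                        range(qoff + lo - lin, qoff + hi - lin + 1)
                    )
            qoff += length
            lin += length
        elif op == "D":
            run_end = lin + length - 1
            for lo_s, hi_s in spans:
                lo = max(lin, lo_s)
                hi = min(run_end, hi_s)
                for p in range(lo, hi + 1):
                    ar.excluded_ref.add(p % L + 1)
            lin += length
        elif op == "I":
            anchor = lin - 1
            if any(lo_s <= anchor <= hi_s for lo_s, hi_s in spans):
                ar.clipped_offsets.update(range(qoff, qoff + length))
            qoff += length
        else:  # soft-clip
            qoff += length
    return ar


@dataclass
class NumtDB:
    """Labelled nuclear-insert decoy sequences for exclusion matching."""

    decoys: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "NumtDB":
        decoys = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(decoys=decoys)

    def __len__(self) -> int:
        return len(self.decoys)


def numt_filter(
    seq: str,
    numt_db: Optional[NumtDB],
    genome: CircularGenome,
    max_distance: int = 2,
) -> bool:
    """True iff the read matches a decoy within ``max_distance`` edits *and*
    strictly better than it matches the mitochondrial reference."""
    if numt_db is None or len(numt_db) == 0:
        return False
    doubled = genome.sequence * 2
    best_decoy = None
    for _, decoy in numt_db.decoys:
        for s in (seq, revcomp(seq)):
            r = edlib.align(s, decoy, mode="HW", k=max_distance)
            d = r["editDistance"]
            if d != -1 and (best_decoy is None or d < best_decoy):
                best_decoy = d
    if best_decoy is None:
        return False
    ref_d = edlib.align(seq, doubled, mode="HW")["editDistance"]
    rc_d = edlib.align(revcomp(seq), doubled, mode="HW")["editDistance"]
    ref_best = min(d for d in (ref_d, rc_d) if d != -1)
    return best_decoy < ref_best


def hvii_softclip(
    ar: AlignedRead,
    genome: CircularGenome,
    cstretch: Region = Region(303, 315, "HVII C-stretch"),
    anchor: int = 262,
    anchor_tol: int = 3,
    min_events: int = 2,
) -> AlignedRead:
    """Clip reverse-strand reads that start at the amplicon boundary near the
    HVII anchor and degrade across the C-stretch.

    Reverse reads whose alignment begins within ``anchor_tol`` of ``anchor``
    and that accumulate >= ``min_events`` non-match alignment events
    (mismatches, insertions, deletions) inside the C-stretch contribute
    counts only up to the first C-stretch position; later reference positions
    are excluded.  Forward-strand reads are never clipped by this rule.
    """
    if ar.strand != "-" or not ar.aligned:
        return ar
    if abs(ar.ref_start - anchor) > anchor_tol:
        return ar
    L = genome.length
    events = 0
    for col in ar.walk(L):
        op, ref_pos = col[0], col[1]
        if not cstretch.contains(ref_pos, L):
            continue
        if op == "M":
            if ar.seq[col[2]] != genome.base(ref_pos):
                events += 1
        else:
            events += 1
    if events < min_events:
        return ar
    ar.flags["hvii_softclipped"] = True
    clip_after = cstretch.start
    for col in ar.walk(L):
        op, ref_pos = col[0], col[1]
        # positions strictly after the first C-stretch base are discarded
        past = (ref_pos - clip_after) % L
        if past == 0 or past > L // 2:
            continue
        if op == "M":
            ar.clipped_offsets.add(col[2])
        elif op == "D":
            ar.excluded_ref.add(ref_pos)
        else:
            qoff, length = col[2]
            ar.clipped_offsets.update(range(qoff, qoff + length))
    return ar


def cigar_string(ar: AlignedRead) -> str:
    return "".join(f"{l}{op}" for op, l in ar.cigar) if ar.cigar else "*"


def write_sam(
    aligned: Sequence[AlignedRead], genome: CircularGenome, path: str | Path
) -> None:
    """Emit a plain-text SAM with the circular contig in the header and
    custom tags for amplicon assignment and filter flags."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": genome.name, "LN": genome.length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for ar in aligned:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = ar.read_id
            seg.query_sequence = ar.seq
            seg.query_qualities = pysam.qualitystring_to_array(ar.qual)
            if ar.aligned:
                seg.reference_id = 0
                seg.reference_start = ar.ref_start - 1
                seg.cigartuples = [
                    ({"M": 0, "I": 1, "D": 2, "S": 4}[op], l) for op, l in ar.cigar
                ]
                seg.flag = 16 if ar.strand == "-" else 0
            else:
                seg.flag = 4
            if ar.amplicon_id:
                seg.set_tag("XA", ar.amplicon_id)
            if ar.flags.get("numt_filtered"):
                seg.set_tag("XN", 1)
            if ar.flags.get("hvii_softclipped"):
                seg.set_tag("XH", 1)
            out.write(seg)
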