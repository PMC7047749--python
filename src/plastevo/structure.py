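"""Inverted-repeat detection and quadripartite structure analysis.

A photosynthetic plastome is organised as LSC–IRb–SSC–IRa: two inverted-repeat copies
(exact or near-exact reverse complements) separating a large and a small single-copy
region.  Degraded genomes may lose the SSC (tripartite, the two IRs head-to-head) or the
IR itself (single-copy-only).  Detection is seed-and-extend over exact k-mer matches
against the reverse complement on the doubled circular sequence, so the result is
invariant under rotation of the origin and under reverse complementation of the genome.

Junctions are named JLB (LSC/IRb), JSB (IRb/SSC), JSA (SSC/IRa) and JLA (IRa/LSC); each
junction position is the 1-based coordinate of the first base of the downstream region.
Junction-gene offsets are signed toward the IR: 0 means the gene overlaps the junction,
negative values put it on the single-copy side.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plastevo.io import PlastomeRecord, revcomp


@dataclass
class QuadripartiteStructure:
    structure_class: str                    # quadripartite | single_copy_only | no_SSC_tripartite
    ir_length: int
    lsc_length: int
    ssc_length: int
    genome_length: int
    #: region name -> (start, end) 1-based inclusive, end may exceed genome length (wrap)
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    #: junction name -> 1-based position of the first base of the downstream region
    junctions: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.structure_class == "quadripartite":
            total = self.lsc_length + self.ssc_length + 2 * self.ir_length
            if total != self.genome_length:
                raise AssertionError(
                    f"region lengths {total} != genome length {self.genome_length}")
            if self.lsc_length < self.ssc_length:
                raise AssertionError("LSC shorter than SSC")


# ---------------------------------------------------------------------------------
# IR detection
# ---------------------------------------------------------------------------------

def detect_inverted_repeat(record: PlastomeRecord, min_len: int = 100,
                           max_mismatch_rate: float = 0.0) -> QuadripartiteStructure:
    """Find the maximal pair of disjoint reverse-complement segments on the circle.

    If the best pair is shorter than ``min_len`` the genome is classed
    ``single_copy_only`` (ir_length 0).  If an IR pair exists but one single-copy arc is
    empty the class is ``no_SSC_tripartite``.  Otherwise the genome is quadripartite,
    with the longer arc called LSC.
    """
    if record.topology != "circular":
        raise ValueError("linear records are unsupported")
    if min_len < 30:
        raise ValueError("min_len must be >= 30")
    seq = record.sequence
    n = len(seq)
    best = _best_ir_pair(seq, min_len)
    if best is not None and max_mismatch_rate > 0:
        best = _extend_with_mismatches(seq, best, max_mismatch_rate)

    if best is None:
        return QuadripartiteStructure(
            structure_class="single_copy_only", ir_length=0, lsc_length=n, ssc_length=0,
            genome_length=n, regions={"LSC": (1, n)}, junctions={})

    (a, b, L) = best  # 0-based starts of the two IR copies (a < b on circle walk), length L
    arc_ab = (b - (a + L)) % n          # arc between copy A end and copy B start
    arc_ba = (a - (b + L)) % n          # arc between copy B end and copy A start
    lsc_len, ssc_len = max(arc_ab, arc_ba), min(arc_ab, arc_ba)

    # orient so the walk reads LSC -> IRb -> SSC -> IRa
    if arc_ba >= arc_ab:
        irb_start, ira_start = a, b       # LSC is the arc before copy A
        lsc_start = (b + L) % n
        ssc_start = (a + L) % n
    else:
        irb_start, ira_start = b, a
        lsc_start = (a + L) % n
        ssc_start = (b + L) % n

    def iv(start0: int, length: int) -> tuple[int, int]:
        s = start0 + 1
        e = start0 + length
        return (s, e if e <= n else e)  # end may exceed n; wrap-aware consumers use mod

    regions = {"LSC": iv(lsc_start, lsc_len), "IRb": iv(irb_start, L)}
    if ssc_len == 0:
        regions["IRa"] = iv(ira_start, L)
        junctions = {"JLB": irb_start + 1, "JSB": (ssc_start % n) + 1,
                     "JSA": ira_start + 1, "JLA": (lsc_start % n) + 1}
        return QuadripartiteStructure(
            structure_class="no_SSC_tripartite", ir_length=L, lsc_length=lsc_len,
            ssc_length=0, genome_length=n, regions=regions, junctions=junctions)
    regions["SSC"] = iv(ssc_start, ssc_len)
    regions["IRa"] = iv(ira_start, L)
    junctions = {"JLB": irb_start + 1, "JSB": (ssc_start % n) + 1,
                 "JSA": ira_start + 1, "JLA": (lsc_start % n) + 1}
    out = QuadripartiteStructure(
        structure_class="quadripartite", ir_length=L, lsc_length=lsc_len,
        ssc_length=ssc_len, genome_length=n, regions=regions, junctions=junctions)
    out.check()
    return out


def _best_ir_pair(seq: str, min_len: int) -> tuple[int, int, int] | None:
    """Maximal exact reverse-complement segment pair on the circular sequence.

    Returns 0-based starts (a, b) with the two copies disjoint on the circle, and the
    common length L; ties resolved toward the smallest single-copy arc, then the
    smallest start (deterministic).  None if the best pair is shorter than ``min_len``.
    """
    n = len(seq)
    if n < 2 * min_len:
        return None
    k = min(31, min_len)
    s2 = seq + seq
    rc2 = revcomp(s2)

    # index k-mers of the reverse complement: rc2[i:i+k] == revcomp of s2 at j = 2n-k-i
    index: dict[str, list[int]] = {}
    for i in range(0, n):
        index.setdefault(s2[i:i + k], []).append(i)

    # seed pairs (a, b): s2[a:a+k] == revcomp(s2[b:b+k]); grouped by antidiagonal a+b
    groups: dict[int, set[int]] = {}
    seen_kmers: set[str] = set()
    for a in range(0, n):
        km = s2[a:a + k]
        if km in seen_kmers:
            continue
        seen_kmers.add(km)
        rkm = revcomp(km)
        hits = index.get(rkm)
        if not hits:
            continue
        starts = index[km]
        for aa in starts:
            for b in hits:
                bb = b
                if bb <= aa:
                    bb += n
                if bb == aa or bb - aa >= n:
                    continue
                groups.setdefault(aa + bb, set()).add(aa)

    candidates: set[tuple[int, int, int]] = set()
    for c, a_set in groups.items():
        a_sorted = sorted(a_set)
        # maximal runs of consecutive a values => maximal exact matches
        run_start = a_sorted[0]
        prev = a_sorted[0]
        runs = []
        for a in a_sorted[1:]:
            if a == prev + 1:
                prev = a
                continue
            runs.append((run_start, prev))
            run_start = prev = a
        runs.append((run_start, prev))
        for lo, hi in runs:
            s = lo
            M = hi - lo + k
            t = c - hi          # start of the partner segment
            if t < s:
                continue        # symmetric duplicate
            for cand in _disjoint_subpairs(s, t, M, n, k):
                candidates.add(cand)

    best, best_key = None, None
    for (a, b, L) in candidates:
        if L < min_len:
            continue
        arc1 = (b - (a + L)) % n
        arc2 = (a - (b + L)) % n
        key = (L, -min(arc1, arc2), -a, -b)
        if best_key is None or key > best_key:
            best, best_key = (a, b, L), key
    return best


def _disjoint_subpairs(s: int, t: int, M: int, n: int, k: int):
    """Derive disjoint circle pairs from a (possibly self-overlapping) match.

    The exact match is s2[s:s+M] == revcomp(s2[t:t+M]) with s <= t.  Overlap means the
    region is self-reverse-complementary (head-to-head IRs with no SSC); the usable pair
    is then the prefix of the first copy against the suffix of the second.
    """
    out = []
    # option 1: anchor A at its left end, B at its right end
    L = min(M, (t - s + M) // 2)
    if L >= k and t + M <= s + n:
        a = s % n
        b = (t + M - L) % n
        out.append((min(a, b), max(a, b), L) if _disjoint(a, b, L, n) else None)
    # option 2 (already disjoint matches): the full pair
    if t >= s + M and (t + M) - s <= n:
        a, b = s % n, t % n
        out.append((min(a, b), max(a, b), M) if _disjoint(a, b, M, n) else None)
    return [x for x in out if x]


def _disjoint(a: int, b: int, L: int, n: int) -> bool:
    if a == b:
        return False
    lo, hi = (a, b) if a < b else (b, a)
    return hi >= lo + L and lo + n >= hi + L


def _extend_with_mismatches(seq: str, pair: tuple[int, int, int],
                            rate: float) -> tuple[int, int, int]:
    """Greedy outward extension tolerating a bounded mismatch fraction.

    The two directions are interleaved so one noisy flank cannot exhaust the mismatch
    budget before the other flank's true repeat is recovered.
    """
    n = len(seq)
    a, b, L = pair
    mism = 0
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "X"}

    def base(i):
        return seq[i % n]

    # a flank stops at a local mismatch cluster (two mismatches within `window`
    # steps): isolated substitutions inside a true repeat pass, random flanking
    # sequence (~75% mismatch) stops almost immediately; a global rate cap remains
    window = 20
    state = {"left": {"open": True, "step": 0, "last_mm": None},
             "right": {"open": True, "step": 0, "last_mm": None}}

    def try_step(side: str) -> bool:
        nonlocal a, b, L, mism
        st = state[side]
        if not st["open"]:
            return False
        if side == "left":      # grow A leftward, pairing with B growing rightward
            ok_geom = _disjoint((a - 1) % n, b % n, L + 1, n)
            add = 0 if ok_geom and comp[base(a - 1)] == base(b + L) else 1
        else:                   # grow A rightward, pairing with B growing leftward
            ok_geom = _disjoint(a % n, (b - 1) % n, L + 1, n)
            add = 0 if ok_geom and comp[base(a + L)] == base(b - 1) else 1
        if not ok_geom or (mism + add) / (L + 1) > rate:
            st["open"] = False
            return False
        if add and st["last_mm"] is not None and st["step"] - st["last_mm"] <= window:
            st["open"] = False
            return False
        if add:
            st["last_mm"] = st["step"]
        st["step"] += 1
        mism += add
        if side == "left":
            a, L = a - 1, L + 1
        else:
            b, L = b - 1, L + 1
        return True

    progress = True
    while progress:
        progress = try_step("left")
        progress = try_step("right") or progress
    return (a % n, b % n, L)


# ---------------------------------------------------------------------------------
# junction genes
# ---------------------------------------------------------------------------------

#: side of each junction on which the IR lies, walking clockwise from the junction
_IR_SIDE = {"JLB": +1, "JSB": -1, "JSA": +1, "JLA": -1}


def junction_genes(record: PlastomeRecord,
                   structure: QuadripartiteStructure) -> list[tuple[str, str, int]]:
    """For each junction: the overlapping feature, else the nearest one.

    Returns (junction, gene, offset) tuples.  Offset 0 means overlap; otherwise the
    signed circular distance to the nearest feature boundary, positive toward the IR.
    """
    if structure.structure_class != "quadripartite":
        raise ValueError("junction analysis requires a quadripartite structure")
    if not record.features:
        raise ValueError("record has no annotated features")
    n = len(record.sequence)
    out = []
    for jname in ("JLB", "JSB", "JSA", "JLA"):
        jpos = structure.junctions[jname]
        best: tuple[int, str] | None = None
        jprev = jpos - 1 if jpos > 1 else n     # the base just upstream of the boundary
        for f in record.features:
            span_s, span_e = f.start, f.end  # end may exceed n for wrap features
            # a junction lies between two bases; a feature containing either abutting
            # base overlaps it
            if _within(jpos, span_s, span_e, n) or _within(jprev, span_s, span_e, n):
                best = (0, f.name)
                break
            d = _signed_junction_distance(jpos, span_s, span_e, n, _IR_SIDE[jname])
            if best is None or abs(d) < abs(best[0]):
                best = (d, f.name)
        out.append((jname, best[1], best[0]))
    return out


def _within(pos: int, s: int, e: int, n: int) -> bool:
    for p in (pos, pos + n):
        if s <= p <= e:
            return True
    return False


def _signed_junction_distance(jpos: int, s: int, e: int, n: int, ir_side: int) -> int:
    """Distance from junction to nearest feature edge, signed toward the IR."""
    d_cw = min((s - jpos) % n, (e - jpos) % n)      # feature reached walking clockwise
    d_ccw = min((jpos - s) % n, (jpos - e) % n)     # walking counterclockwise
    if d_cw <= d_ccw:
        return d_cw * ir_side
    return -d_ccw * ir_side


# ---------------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """GC percentage over A/C/G/T (N excluded from the denominator)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * gc / denom


@dataclass
class CompositionSummary:
    gc_whole: float
    gc_by_region: dict[str, float]
    at_bias_delta: float    # baseline GC minus observed GC; positive = AT-shifted


def composition_summary(record: PlastomeRecord, structure: QuadripartiteStructure,
                        baseline_gc: float = 36.40) -> CompositionSummary:
    gc_whole = gc_content(record.sequence)
    by_region = {}
    for name, (s, e) in structure.regions.items():
        by_region[name] = gc_content(record.extract(s, e))
    return CompositionSummary(gc_whole=gc_whole, gc_by_region=by_region,
                              at_bias_delta=baseline_gc - gc_whole)


# ---------------------------------------------------------------------------------
# per-taxon structure table
# ---------------------------------------------------------------------------------

def structure_table(records: list[PlastomeRecord], min_len: int = 100,
                    max_mismatch_rate: float = 0.0) -> pd.DataFrame:
    """One row per record: lengths, structure class and GC, plus a min/max/mean row."""
    if not records:
        raise ValueError("no records")
    rows = []
    for rec in records:
        st = detect_inverted_repeat(rec, min_len=min_len, max_mismatch_rate=max_mismatch_rate)
        rows.append({"taxon": rec.taxon, "accession": rec.accession,
                     "length_bp": len(rec.sequence), "lsc_bp": st.lsc_length,
                     "ssc_bp": st.ssc_length, "ir_bp": st.ir_length,
                     "gc_percent": round(gc_content(rec.sequence), 2),
                     "structure_class": st.structure_class})
    df = pd.DataFrame(rows)
    return add_length_summary(df)


def add_length_summary(df: pd.DataFrame, column: str = "length_bp") -> pd.DataFrame:
    """Append min/max/mean summary rows over a per-taxon length table."""
    numeric = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    summary = []
    for stat, fn in (("min", np.min), ("max", np.max), ("mean", np.mean)):
        row = {c: (fn(df[c].dropna()) if c in numeric else "") for c in df.columns}
        row["taxon"] = f"<{stat}>"
        summary.append(row)
    return pd.concat([df, pd.DataFrame(summary)], ignore_index=True)


def length_summary(df: pd.DataFrame, column: str = "length_bp") -> dict[str, float]:
    """min/max/mean of a length column over per-taxon rows (summary rows excluded)."""
    data = df[~df["taxon"].astype(str).str.startswith("<")][column].dropna()
    return {"min": float(data.min()), "max": float(data.max()), "mean": float(data.mean())}
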