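"""Raw paired-end FASTQ to variant-assigned fragments.

The cleanup contract mirrors the published command-line pipeline
(adapter removal with ``-m 10``, pair joining, ``-q 20 -p 90`` quality
filtering, exact-sequence duplicate collapse) re-implemented as plain
functions so the whole pipeline is self-contained and unit-testable.
Stage order is fixed: trim -> merge -> quality -> dedup -> strip -> assign,
and per-stage counters conserve read counts.

Assignment is mismatch-only (no indels) against the full variant reference
set: a read is assigned iff exactly one (variant, start) placement attains
the minimum Hamming distance and that distance is at most ``d_max``.
Ties — including reads that do not span a randomized group and therefore
match every group-mate equally well — are unassigned.  Two implementations
share this contract: :class:`ExhaustiveAssigner` (reference semantics,
scans every placement) and :class:`BackboneAssigner` (decomposes distances
into a backbone term plus per-group terms; exactly equivalent and much
faster on full 766-variant libraries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import revcomp, to_dna
from .library_design import GROUP_WIDTH, BackboneSpec, VariantLibrary

OS = "OS"
PRODUCT = "PRODUCT"
BARCODE_LEN = {OS: 4, PRODUCT: 6}

_ACGT = frozenset(b"ACGT")


class ReadRecord(NamedTuple):
    read_id: str
    sequence: str
    quality: str


class ProcessedFragment(NamedTuple):
    variant_id: str
    library_kind: str  # OS | PRODUCT
    start: int  # 1-based 5'-end index on the variant sequence
    length: int
    barcode: str


class Assignment(NamedTuple):
    variant_id: str
    start: int
    distance: int


# ---------------------------------------------------------------------------
# adapter trimming


def find_adapter(
    seq: str,
    adapter: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> int | None:
    """Start index of the adapter occurrence closest to the 3' end, or None.

    An occurrence may be a full adapter anywhere in the read or a 3'-terminal
    prefix of the adapter, with at most ``floor(max_error_rate * overlap)``
    mismatches and no indels.
    """
    n, la = len(seq), len(adapter)
    if la == 0 or n < min_overlap:
        return None
    # 3'-terminal partial overlaps, closest to the 3' end first
    lo_partial = max(n - la + 1, 0)
    for start in range(n - min_overlap, lo_partial - 1, -1):
        ov = n - start
        allowed = int(max_error_rate * ov)
        mm = 0
        for a, b in zip(seq[start:], adapter):
            if a != b:
                mm += 1
                if mm > allowed:
                    break
        else:
            return start
    # full-length occurrences, rightmost wins
    if n >= la:
        if seq.endswith(adapter):  # rightmost possible full window
            return n - la
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        ad = np.frombuffer(adapter.encode(), dtype=np.uint8)
        windows = sliding_window_view(arr, la)
        mm = (windows != ad).sum(axis=1)
        valid = np.flatnonzero(mm <= int(max_error_rate * la))
        if valid.size:
            return int(valid[-1])
    return None


def trim_adapter(read: ReadRecord, adapter: str, **kw) -> ReadRecord:
    pos = find_adapter(read.sequence, adapter, **kw)
    if pos is None:
        return read
    return ReadRecord(read.read_id, read.sequence[:pos], read.quality[:pos])


def trim_adapters(
    pair: tuple[ReadRecord, ReadRecord],
    adapter_r1: str,
    adapter_r2: str,
    min_length: int = 10,
    max_error_rate: float = 0.1,
) -> tuple[ReadRecord, ReadRecord] | None:
    """Trim 3' adapters from both mates; discard the pair if either mate
    drops below ``min_length`` (the published ``-m 10``).  Untrimmable reads
    pass through unchanged."""
    r1 = trim_adapter(pair[0], adapter_r1, max_error_rate=max_error_rate)
    r2 = trim_adapter(pair[1], adapter_r2, max_error_rate=max_error_rate)
    if len(r1.sequence) < min_length or len(r2.sequence) < min_length:
        return None
    return r1, r2


# ---------------------------------------------------------------------------
# pair merging


def merge_pairs(
    pair: tuple[ReadRecord, ReadRecord],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> ReadRecord | None:
    """Join two trimmed mates into one read through their 3' overlap.

    The 3' end of R1 is aligned against the reverse complement of R2 at every
    overlap length >= ``min_overlap``.  Exact overlaps are preferred (longest
    first); otherwise the longest overlap with a mismatch fraction at most
    ``max_mismatch_frac`` wins.  At conflicting positions the higher-quality
    base is kept (R1 on quality ties).  Returns None when no admissible
    overlap exists.
    """
    r1, r2 = pair
    s1, q1 = r1.sequence, r1.quality
    s2 = revcomp(r2.sequence)
    q2 = r2.quality[::-1]
    l1, l2 = len(s1), len(s2)
    max_ov = min(l1, l2)
    if max_ov < min_overlap:
        return None
    best_ov = None
    for ov in range(max_ov, min_overlap - 1, -1):  # exact pass
        if s1[l1 - ov :] == s2[:ov]:
            best_ov = ov
            break
    if best_ov is None:  # mismatch-tolerant pass
        for ov in range(max_ov, min_overlap - 1, -1):
            allowed = int(max_mismatch_frac * ov)
            mm = 0
            t1 = s1[l1 - ov :]
            for a, b in zip(t1, s2[:ov]):
                if a != b:
                    mm += 1
                    if mm > allowed:
                        break
            else:
                best_ov = ov
                break
    if best_ov is None:
        return None
    ov = best_ov
    head_s, head_q = s1[: l1 - ov], q1[: l1 - ov]
    tail_s, tail_q = s2[ov:], q2[ov:]
    mid_s = []
    mid_q = []
    for i in range(ov):
        a, qa = s1[l1 - ov + i], q1[l1 - ov + i]
        b, qb = s2[i], q2[i]
        if a == b:
            mid_s.append(a)
            mid_q.append(max(qa, qb))
        elif qb > qa:
            mid_s.append(b)
            mid_q.append(qb)
        else:
            mid_s.append(a)
            mid_q.append(qa)
    return ReadRecord(
        r1.read_id, head_s + "".join(mid_s) + tail_s, head_q + "".join(mid_q) + tail_q
    )


# ---------------------------------------------------------------------------
# quality filter / dedup / barcode


def quality_filter(read: ReadRecord, min_q: int = 20, min_frac: float = 0.9) -> bool:
    """Keep iff at least ``min_frac`` of bases have phred >= ``min_q``
    (boundary inclusive; phred+33 encoding)."""
    q = read.quality
    if not q:
        return False
    thr = chr(33 + min_q)
    if min(q) >= thr:
        return True
    good = sum(1 for c in q if c >= thr)
    return good >= min_frac * len(q)


def deduplicate(reads: Iterable[ReadRecord]) -> Iterator[ReadRecord]:
    """One representative per distinct sequence string (first occurrence).

    Runs before barcode stripping, so the random-mer still distinguishes
    molecules with identical fragments.
    """
    seen: set[str] = set()
    for r in reads:
        if r.sequence not in seen:
            seen.add(r.sequence)
            yield r


def strip_barcode(
    read: ReadRecord, library_kind: str
) -> tuple[ReadRecord, str] | None:
    """Remove and return the leading random-mer (6 nt products, 4 nt OS)."""
    k = BARCODE_LEN[library_kind]
    if len(read.sequence) <= k:
        return None
    return (
        ReadRecord(read.read_id, read.sequence[k:], read.quality[k:]),
        read.sequence[:k],
    )


# ---------------------------------------------------------------------------
# variant assignment


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class ExhaustiveAssigner:
    """Reference assigner: scans every (variant, start) placement.

    Accepts :class:`VariantLibrary` objects or plain ``(id, sequence)``
    pairs; sequences are compared in DNA alphabet.
    """

    def __init__(
        self,
        libraries: VariantLibrary | Iterable[VariantLibrary] | Sequence[tuple[str, str]],
        d_max: int = 2,
    ) -> None:
        self.d_max = d_max
        entries: list[tuple[str, str]] = []
        if isinstance(libraries, VariantLibrary):
            libraries = [libraries]
        for item in libraries:
            if isinstance(item, VariantLibrary):
                entries.extend(
                    (v.variant_id, to_dna(v.full_sequence)) for v in item.variants
                )
            else:
                vid, seq = item
                entries.append((vid, to_dna(seq)))
        # group equal-length references into stacked matrices
        self._batches: list[tuple[list[str], np.ndarray]] = []
        by_len: dict[int, list[tuple[str, str]]] = {}
        for vid, seq in entries:
            by_len.setdefault(len(seq), []).append((vid, seq))
        for L in sorted(by_len):
            ids = [vid for vid, _ in by_len[L]]
            mat = np.vstack([_encode(seq) for _, seq in by_len[L]])
            self._batches.append((ids, mat))

    def assign(self, seq: str) -> Assignment | None:
        read = _encode(to_dna(seq))
        m = read.size
        if m == 0:
            return None
        best = self.d_max + 1
        winners: set[tuple[str, int]] = set()
        for ids, mat in self._batches:
            L = mat.shape[1]
            if L < m:
                continue
            win = sliding_window_view(mat, m, axis=1)  # (n, L-m+1, m)
            d = (win != read).sum(axis=2)
            dmin = int(d.min())
            if dmin > best:
                continue
            if dmin < best:
                best = dmin
                winners.clear()
            vi, si = np.nonzero(d == dmin)
            for v, s in zip(vi, si):
                winners.add((ids[int(v)], int(s) + 1))
        if best > self.d_max or len(winners) != 1:
            return None
        (vid, start), = winners
        return Assignment(vid, start, best)


class _BackboneIndex:
    def __init__(self, library: VariantLibrary) -> None:
        bb = library.backbone
        self.wt = _encode(to_dna(bb.sequence))
        self.L = bb.length
        self.group_ids = [g.group_id for g in bb.groups]
        self.pos0 = [np.array([p - 1 for p in g.positions]) for g in bb.groups]
        self.n_groups = len(self.pos0)
        self.all_pos = np.concatenate(self.pos0)  # (n_groups*4,)
        self.wt_at_pos = self.wt[self.all_pos]
        self.is_group = np.zeros(self.L, dtype=bool)
        for pos in self.pos0:
            self.is_group[pos] = True
        wt_variant = next(v for v in library.variants if v.wt)
        self.lookup: dict[tuple[int, str], str] = {}
        for v in library.variants:
            self.lookup[(v.group_id, to_dna(v.substituted_nt))] = v.variant_id
        for g in bb.groups:  # WT is deduplicated: map every group's WT mer to it
            self.lookup.setdefault((g.group_id, to_dna(g.wt_nt)), wt_variant.variant_id)
        self._geom: dict[int, tuple] = {}  # read-length -> cached geometry

    def geometry(self, m: int):
        """Read-length-dependent tensors: WT windows, non-group masks, and the
        read-index matrix of every group position at every start."""
        cached = self._geom.get(m)
        if cached is not None:
            return cached
        S = self.L - m + 1
        win = sliding_window_view(self.wt, m).copy()  # (S, m)
        notg = ~sliding_window_view(self.is_group, m)
        starts = np.arange(S)
        ridx = self.all_pos[:, None] - starts[None, :]  # read index of pos p at start s
        valid = (ridx >= 0) & (ridx < m)
        ridx_c = np.clip(ridx, 0, m - 1)
        cov = valid.reshape(self.n_groups, GROUP_WIDTH, S).sum(axis=1)  # (G, S)
        cached = (S, win, notg, ridx_c, valid, cov)
        self._geom[m] = cached
        return cached


class BackboneAssigner:
    """Fast assigner exploiting the backbone structure of the library.

    Every variant differs from its backbone only at one group's four
    positions, so the Hamming distance of a read placement decomposes into a
    group-masked backbone term plus per-group terms; the best variant within
    each group matches the read exactly at the covered group positions.  The
    global unique-minimum rule is then evaluated over (group, start) cells.
    Results are memoized per fragment string (distinct molecules of one
    cleavage product differ only in their barcode).
    """

    def __init__(
        self,
        libraries: VariantLibrary | Iterable[VariantLibrary],
        d_max: int = 2,
        memoize: bool = True,
    ) -> None:
        if isinstance(libraries, VariantLibrary):
            libraries = [libraries]
        self.d_max = d_max
        self._indexes = [_BackboneIndex(lib) for lib in libraries]
        self._memo: dict[str, Assignment | None] | None = {} if memoize else None

    def assign(self, seq: str) -> Assignment | None:
        if self._memo is not None and seq in self._memo:
            return self._memo[seq]
        result = self._scan(to_dna(seq))
        if self._memo is not None:
            self._memo[seq] = result
        return result

    def _scan(self, seq: str) -> Assignment | None:
        read = _encode(seq)
        m = read.size
        if m == 0:
            return None
        pure_acgt = not (set(seq) - {"A", "C", "G", "T"})
        best = self.d_max + 1
        results: list[tuple[int, _BackboneIndex, int, int, np.ndarray]] = []
        for idx in self._indexes:
            if idx.L < m:
                continue
            S, win, notg, ridx, valid, cov = idx.geometry(m)
            neq = win != read  # (S, m)
            mm = (neq & notg).sum(axis=1)  # backbone mismatches, groups masked
            rb = read[ridx]  # (n_pos, S) read base at each group position
            mism = (rb != idx.wt_at_pos[:, None]) & valid
            H = mism.reshape(idx.n_groups, GROUP_WIDTH, S).sum(axis=1)  # (G, S)
            if pure_acgt:
                NN = None
            else:
                bad = ~np.isin(rb, np.frombuffer(b"ACGT", dtype=np.uint8)) & valid
                NN = bad.reshape(idx.n_groups, GROUP_WIDTH, S).sum(axis=1)
            # best achievable distance for a group-g variant starting at s:
            # masked backbone mismatches + other groups' read-vs-WT mismatches
            # (+ unmatchable non-ACGT bases inside this group)
            d = mm[None, :] + H.sum(axis=0)[None, :] - H
            if NN is not None:
                d = d + NN
            dmin = int(d.min())
            if dmin <= best:
                results.append((dmin, idx, S, m, d))
                best = min(best, dmin)
        if best > self.d_max:
            return None
        winners: set[tuple[str, int]] = set()
        for dmin, idx, S, m_, d in results:
            if dmin > best:
                continue
            _, _, _, _, valid, cov = idx.geometry(m_)
            for gi, s in zip(*np.nonzero(d == best)):
                gi, s = int(gi), int(s)
                if cov[gi, s] < GROUP_WIDTH:
                    return None  # group not fully covered: >1 variant ties
                mer = "".join(seq[p - s] for p in idx.pos0[gi])
                vid = idx.lookup.get((idx.group_ids[gi], mer))
                if vid is None:  # non-ACGT base inside the group: no unique mer
                    return None
                winners.add((vid, s + 1))
        if len(winners) != 1:
            return None
        (vid, start), = winners
        return Assignment(vid, start, best)


def assign_to_variant(
    seq: str,
    libraries: VariantLibrary | Iterable[VariantLibrary],
    d_max: int = 2,
) -> Assignment | None:
    """One-shot assignment (builds an :class:`ExhaustiveAssigner`); for bulk
    work construct an assigner once and reuse it."""
    return ExhaustiveAssigner(libraries, d_max=d_max).assign(seq)


# ---------------------------------------------------------------------------
# full per-library pipeline


@dataclass
class StageCounters:
    """Read accounting through the fixed stage order; counts conserve."""

    input_pairs: int = 0
    discarded_trim: int = 0
    discarded_merge: int = 0
    discarded_quality: int = 0
    removed_duplicates: int = 0
    discarded_short_barcode: int = 0
    unassigned: int = 0
    assigned: int = 0

    def conserved(self) -> bool:
        return self.input_pairs == (
            self.discarded_trim
            + self.discarded_merge
            + self.discarded_quality
            + self.removed_duplicates
            + self.discarded_short_barcode
            + self.unassigned
            + self.assigned
        )

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def process_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    library_kind: str,
    assigner: BackboneAssigner | ExhaustiveAssigner,
    adapter_r1: str,
    adapter_r2: str,
    min_length: int = 10,
) -> tuple[list[ProcessedFragment], StageCounters]:
    """Run trim -> merge -> quality -> dedup -> strip -> assign on one library."""
    c = StageCounters()
    merged: list[ReadRecord] = []
    for pair in pairs:
        c.input_pairs += 1
        trimmed = trim_adapters(pair, adapter_r1, adapter_r2, min_length=min_length)
        if trimmed is None:
            c.discarded_trim += 1
            continue
        joined = merge_pairs(trimmed)
        if joined is None:
            c.discarded_merge += 1
            continue
        if not quality_filter(joined):
            c.discarded_quality += 1
            continue
        merged.append(joined)
    fragments: list[ProcessedFragment] = []
    n_unique = 0
    for read in deduplicate(merged):
        n_unique += 1
        stripped = strip_barcode(read, library_kind)
        if stripped is None:
            c.discarded_short_barcode += 1
            continue
        frag, barcode = stripped
        hit = assigner.assign(frag.sequence)
        if hit is None:
            c.unassigned += 1
            continue
        c.assigned += 1
        fragments.append(
            ProcessedFragment(
                variant_id=hit.variant_id,
                library_kind=library_kind,
                start=hit.start,
                length=len(frag.sequence),
                barcode=barcode,
            )
        )
    c.removed_duplicates = len(merged) - n_unique
    return fragments, c
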