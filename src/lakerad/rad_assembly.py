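"""De novo RAD locus assembly and cleaning.

Implements the read-processing chain for single-end ddRAD data:
demultiplexing on in-line barcodes with cut-site validation, adapter/quality
trimming, greedy identity clustering of reads into per-individual loci,
low-complexity masking, construction of a shared de novo reference from loci
present in a minimum fraction of individuals, contaminant screening (GC
content and exact k-mer matches), and unique gapless assignment of reads back
to the reference.

All sequence comparisons are gapless and vectorized over uint8-encoded
sequences; every read that is dropped at any stage is logged with a reason
code so that reads in = reads assigned + reads discarded holds exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReadRecord",
    "Locus",
    "LocusCatalog",
    "demultiplex",
    "trim_reads",
    "cluster_loci",
    "dust_mask",
    "mask_and_filter_locus",
    "build_reference",
    "screen_contaminants",
    "assign_reads",
]

# ---------------------------------------------------------------------------
# sequence encoding helpers

_BASES = "ACGT"


def seq_to_u8(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def u8_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int((seq_to_u8(a) != seq_to_u8(b)).sum())


def gc_fraction(seq: str) -> float:
    """G+C fraction over called (non-N) bases."""
    called = sum(seq.count(b) for b in _BASES)
    if called == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / called


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ReadRecord:
    """A single sequencing read.

    ``sequence`` and ``qualities`` (Phred+33 string) always have equal
    length; ``individual`` is filled in by :func:`demultiplex`.
    """

    id: str
    sequence: str
    qualities: str
    individual: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass
class Locus:
    locus_id: str
    representative: str
    support: int
    # per-individual read stacks: individual -> list of read sequences
    stacks: dict = field(default_factory=dict)
    flags: set = field(default_factory=set)
    masked_positions: tuple = ()
    n_individuals: int = 0


@dataclass
class LocusCatalog:
    """A collection of RAD loci with filter status.

    Retained loci are those with an empty flag set.
    """

    loci: list

    @property
    def retained(self) -> list:
        return [l for l in self.loci if not l.flags]

    def get(self, locus_id: str) -> Locus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)


# ---------------------------------------------------------------------------
# demultiplexing


def _validate_barcodes(barcodes: dict, max_mismatch: int) -> int:
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) != 1:
        raise ValueError("all barcodes must have the same length")
    (bl,) = lengths
    items = list(barcodes.values())
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if hamming(items[i], items[j]) <= 2 * max_mismatch:
                raise ValueError(
                    f"ambiguous barcode table: {items[i]} and {items[j]} are "
                    f"within {2 * max_mismatch} mismatches of each other"
                )
    return bl


def demultiplex(
    reads,
    barcode_map: dict,
    max_mismatch: int = 1,
    cut_remnant: str = "GCATGC",
):
    """Partition reads by in-line barcode and validate the cut-site remnant.

    A read is assigned to the unique barcode within ``max_mismatch``
    mismatches of its prefix, and only kept when the expected restriction
    cut-site remnant follows the barcode exactly.  Barcode and remnant are
    stripped from the output read.

    Parameters
    ----------
    reads : iterable of ReadRecord
    barcode_map : dict
        individual -> barcode sequence.  Barcodes must be pairwise more than
        ``2 * max_mismatch`` mismatches apart (rejected at load otherwise).

    Returns
    -------
    (assigned, discards)
        ``assigned`` maps individual -> list of trimmed ReadRecords;
        ``discards`` is a list of ``(read_id, reason)`` tuples with reasons
        ``"barcode_not_found"`` or ``"cut_site_not_found"``.
    """
    bl = _validate_barcodes(barcode_map, max_mismatch)
    exact = {bc: ind for ind, bc in barcode_map.items()}
    bc_mat = np.stack([seq_to_u8(bc) for bc in barcode_map.values()])
    bc_inds = list(barcode_map.keys())
    rl = len(cut_remnant)

    assigned: dict = {ind: [] for ind in barcode_map}
    discards: list = []
    for read in reads:
        prefix = read.sequence[:bl]
        ind = exact.get(prefix)
        if ind is None and max_mismatch > 0 and len(prefix) == bl:
            dists = (bc_mat != seq_to_u8(prefix)).sum(axis=1)
            hits = np.nonzero(dists <= max_mismatch)[0]
            if hits.size == 1:
                ind = bc_inds[int(hits[0])]
        if ind is None:
            discards.append((read.id, "barcode_not_found"))
            continue
        if read.sequence[bl : bl + rl] != cut_remnant:
            discards.append((read.id, "cut_site_not_found"))
            continue
        assigned[ind].append(
            ReadRecord(
                id=read.id,
                sequence=read.sequence[bl + rl :],
                qualities=read.qualities[bl + rl :],
                individual=ind,
            )
        )
    return assigned, discards


# ---------------------------------------------------------------------------
# trimming


def trim_reads(
    reads,
    adapter_seq: str | None = None,
    min_quality: int = 20,
    min_length: int = 30,
    min_adapter_overlap: int = 5,
):
    """Remove 3' adapter matches and low-quality tails; drop short reads.

    The adapter is removed at its first full occurrence, or where a suffix of
    the read matches a prefix of the adapter with at least
    ``min_adapter_overlap`` bases.  Trailing bases with Phred quality below
    ``min_quality`` are then removed.  Reads shorter than ``min_length``
    after trimming are dropped and logged.

    Returns ``(trimmed_reads, discards)``.
    """
    trimmed: list = []
    discards: list = []
    for read in reads:
        seq, qual = read.sequence, read.qualities
        if adapter_seq:
            pos = seq.find(adapter_seq)
            if pos >= 0:
                seq, qual = seq[:pos], qual[:pos]
            else:
                # partial adapter running off the 3' end
                max_ov = min(len(adapter_seq) - 1, len(seq))
                for ov in range(max_ov, min_adapter_overlap - 1, -1):
                    if seq.endswith(adapter_seq[:ov]):
                        seq, qual = seq[:-ov], qual[:-ov]
                        break
        end = len(seq)
        while end > 0 and (ord(qual[end - 1]) - 33) < min_quality:
            end -= 1
        seq, qual = seq[:end], qual[:end]
        if len(seq) < min_length:
            discards.append((read.id, "too_short"))
            continue
        trimmed.append(
            ReadRecord(id=read.id, sequence=seq, qualities=qual, individual=read.individual)
        )
    return trimmed, discards


# ---------------------------------------------------------------------------
# greedy identity clustering

_PAD_SEQ = 1  # sentinel pad values chosen so padding never matches
_PAD_CEN = 0


class _CentroidSet:
    """Growing matrix of cluster centroids supporting vectorized identity."""

    def __init__(self, capacity: int = 256, width: int = 0):
        self.mat = np.full((capacity, width), _PAD_CEN, dtype=np.uint8)
        self.lengths = np.zeros(capacity, dtype=np.int64)
        self.n = 0

    def _grow(self, width: int) -> None:
        cap, w = self.mat.shape
        new_w = max(w, width)
        new_cap = cap if self.n < cap else cap * 2
        if new_cap != cap or new_w != w:
            mat = np.full((new_cap, new_w), _PAD_CEN, dtype=np.uint8)
            mat[: self.n, :w] = self.mat[: self.n]
            self.mat = mat
            lengths = np.zeros(new_cap, dtype=np.int64)
            lengths[: self.n] = self.lengths[: self.n]
            self.lengths = lengths

    def add(self, arr: np.ndarray) -> int:
        self._grow(arr.size)
        self.mat[self.n, : arr.size] = arr
        self.mat[self.n, arr.size :] = _PAD_CEN
        self.lengths[self.n] = arr.size
        self.n += 1
        return self.n - 1

    def first_match(self, arr: np.ndarray, identity_threshold: float) -> int | None:
        """Index of the first (oldest) centroid with identity >= threshold.

        Identity is matches over the length of the shorter sequence
        (comparison is gapless, anchored at position 0).
        """
        if self.n == 0:
            return None
        w = self.mat.shape[1]
        probe = np.full(w, _PAD_SEQ, dtype=np.uint8)
        probe[: min(arr.size, w)] = arr[:w]
        matches = (self.mat[: self.n] == probe).sum(axis=1)
        minlen = np.minimum(self.lengths[: self.n], arr.size)
        ident = matches / np.maximum(minlen, 1)
        hits = np.nonzero(ident >= identity_threshold)[0]
        return int(hits[0]) if hits.size else None


def _consensus(seqs_counts: list) -> str:
    """Per-column majority consensus over (sequence, weight) pairs, N on ties."""
    width = max(len(s) for s, _ in seqs_counts)
    counts = np.zeros((width, 256), dtype=np.int64)
    for seq, w in seqs_counts:
        arr = seq_to_u8(seq)
        counts[np.arange(arr.size), arr] += w
    best = counts.argmax(axis=1)
    bestcount = counts.max(axis=1)
    # tie -> N
    counts[np.arange(width), best] = -1
    tie = counts.max(axis=1) == bestcount
    out = best.astype(np.uint8)
    out[tie] = ord("N")
    return u8_to_seq(out)


def cluster_loci(reads, identity_threshold: float = 0.90, min_support: int = 3):
    """Greedy centroid clustering of one individual's reads into loci.

    Unique read sequences are processed in abundance-then-lexicographic
    order; each joins the first existing centroid whose gapless identity is
    at least ``identity_threshold``, otherwise it founds a new centroid.
    Clusters supported by fewer than ``min_support`` reads are discarded.
    The cluster representative is the per-column majority consensus of its
    member reads (``N`` on ties).

    Returns a list of dicts ``{"representative", "support", "reads"}``
    sorted by descending support then representative sequence (a
    deterministic order independent of input read order).
    """
    counts = Counter(r.sequence for r in reads)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    centroids = _CentroidSet()
    members: list = []  # per centroid: list of (seq, count)
    for seq, cnt in ordered:
        arr = seq_to_u8(seq)
        idx = centroids.first_match(arr, identity_threshold)
        if idx is None:
            centroids.add(arr)
            members.append([(seq, cnt)])
        else:
            members[idx].append((seq, cnt))
    clusters = []
    for mem in members:
        support = sum(c for _, c in mem)
        if support < min_support:
            continue
        clusters.append(
            {
                "representative": _consensus(mem),
                "support": support,
                "reads": mem,
            }
        )
    clusters.sort(key=lambda c: (-c["support"], c["representative"]))
    return clusters


# ---------------------------------------------------------------------------
# low-complexity masking and N filtering


def dust_score(seq: str, k: int = 3) -> float:
    """DUST-style triplet redundancy score of a sequence window.

    score = sum_t c_t (c_t - 1) / 2 / (T - 1) over counts c_t of the T
    triplets free of N (already-masked positions are not re-scored).
    A random window scores well below 1; a perfect dinucleotide repeat of
    width 64 scores ~15.
    """
    w = len(seq)
    if w <= k:
        return 0.0
    trip = Counter(
        seq[i : i + k] for i in range(w - k + 1) if "N" not in seq[i : i + k]
    )
    total = sum(trip.values())
    if total < 2:
        return 0.0
    s = sum(c * (c - 1) / 2 for c in trip.values())
    return s / (total - 1)


def dust_mask(seq: str, window: int = 64, threshold: float = 2.0) -> str:
    """Replace low-complexity windows (DUST score > threshold) with N."""
    n = len(seq)
    masked = bytearray(seq.encode("ascii"))
    step = max(window // 2, 1)
    starts = list(range(0, max(n - window, 0) + 1, step))
    if not starts:
        starts = [0]
    elif starts[-1] != n - window and n > window:
        starts.append(n - window)  # cover the 3' tail
    for s in starts:
        win = seq[s : s + window]
        if dust_score(win) > threshold:
            for i in range(s, min(s + window, n)):
                masked[i] = ord("N")
    return masked.decode("ascii")


def mask_and_filter_locus(
    sequence: str,
    max_N_fraction: float = 0.6,
    complexity_threshold: float = 2.0,
    window: int = 64,
):
    """Mask low-complexity runs, then apply the N-fraction discard rule.

    Returns ``(masked_sequence, flags)``; ``flags`` contains
    ``"low_complexity"`` when any window was masked and ``"high_N"`` when
    more than ``max_N_fraction`` of positions are N after masking (the locus
    is discarded in that case; at exactly the threshold it is retained).
    """
    masked = dust_mask(sequence, window=window, threshold=complexity_threshold)
    flags = set()
    if masked != sequence:
        flags.add("low_complexity")
    n_frac = masked.count("N") / max(len(masked), 1)
    if n_frac > max_N_fraction:
        flags.add("high_N")
    return masked, flags


# ---------------------------------------------------------------------------
# shared reference


def build_reference(
    per_individual_catalogs: dict,
    min_share_fraction: float = 0.7,
    identity_threshold: float = 0.90,
    max_N_fraction: float = 0.6,
    complexity_threshold: float = 2.0,
):
    """Cross-individual clustering of locus representatives into a reference.

    Representatives from all individuals are clustered with the same greedy
    identity rule used within individuals; a cross-individual locus enters
    the de novo reference iff it is present in at least
    ``min_share_fraction`` of the individuals (fraction comparison, no
    ceiling).  Masking and the N-fraction rule are applied to each consensus.

    Parameters
    ----------
    per_individual_catalogs : dict
        individual -> list of clusters from :func:`cluster_loci`.

    Returns
    -------
    LocusCatalog with locus ids ``L{i:06d}``; loci failing the sharing rule
    carry flag ``"not_shared"``, masked-out loci ``"high_N"``.
    """
    if not per_individual_catalogs or all(
        not cl for cl in per_individual_catalogs.values()
    ):
        raise ValueError("empty catalogs: nothing to build a reference from")
    n_ind = len(per_individual_catalogs)
    # pool representatives, keep provenance
    entries = []  # (rep, support, individual)
    for ind, clusters in per_individual_catalogs.items():
        for c in clusters:
            entries.append((c["representative"], c["support"], ind))
    entries.sort(key=lambda e: (-e[1], e[0]))
    centroids = _CentroidSet()
    groups: list = []
    for rep, support, ind in entries:
        arr = seq_to_u8(rep)
        idx = centroids.first_match(arr, identity_threshold)
        if idx is None:
            centroids.add(arr)
            groups.append([(rep, support, ind)])
        else:
            groups[idx].append((rep, support, ind))
    loci = []
    ordered = sorted(
        groups,
        key=lambda g: (-sum(s for _, s, _ in g), min(r for r, _, _ in g)),
    )
    for i, grp in enumerate(ordered):
        inds = {ind for _, _, ind in grp}
        consensus = _consensus([(r, s) for r, s, _ in grp])
        masked, flags = mask_and_filter_locus(
            consensus,
            max_N_fraction=max_N_fraction,
            complexity_threshold=complexity_threshold,
        )
        if len(inds) / n_ind < min_share_fraction:
            flags.add("not_shared")
        loci.append(
            Locus(
                locus_id=f"L{i:06d}",
                representative=masked,
                support=sum(s for _, s, _ in grp),
                flags=flags,
                masked_positions=tuple(
                    j for j, b in enumerate(masked) if b == "N"
                ),
                n_individuals=len(inds),
            )
        )
    return LocusCatalog(loci=loci)


# ---------------------------------------------------------------------------
# contaminant screening


def screen_contaminants(
    reference: LocusCatalog,
    gc_max: float = 0.55,
    contaminant_kmers: set | None = None,
    k: int = 21,
    min_kmer_hits: int = 1,
):
    """Flag reference loci that look microbial.

    Loci with GC fraction strictly above ``gc_max`` get flag ``"high_GC"``;
    loci sharing at least ``min_kmer_hits`` exact k-mers with a user-supplied
    contaminant sequence set get flag ``"contaminant_kmer"``.  The operation
    is idempotent.  Returns ``(reference, removed)`` where ``removed`` lists
    ``(locus_id, reason)``.
    """
    removed = []
    for locus in reference.loci:
        if "not_shared" in locus.flags or "high_N" in locus.flags:
            continue
        if gc_fraction(locus.representative) > gc_max:
            if "high_GC" not in locus.flags:
                locus.flags.add("high_GC")
            removed.append((locus.locus_id, "high_GC"))
        if contaminant_kmers:
            seq = locus.representative
            hits = 0
            for j in range(len(seq) - k + 1):
                if seq[j : j + k] in contaminant_kmers:
                    hits += 1
                    if hits >= min_kmer_hits:
                        break
            if hits >= min_kmer_hits:
                locus.flags.add("contaminant_kmer")
                removed.append((locus.locus_id, "contaminant_kmer"))
    return reference, removed


def kmer_set(sequences, k: int = 21) -> set:
    """All k-mers of an iterable of contaminant sequences."""
    out: set = set()
    for seq in sequences:
        for j in range(len(seq) - k + 1):
            out.add(seq[j : j + k])
    return out


# ---------------------------------------------------------------------------
# unique read assignment


def assign_reads(
    reads_per_individual: dict,
    reference: LocusCatalog,
    max_mismatches: int = 5,
    chunk: int = 2048,
):
    """Assign reads to reference loci by gapless unique best match.

    Each read is aligned at coordinate 0 against every retained reference
    locus; it is assigned when its best mismatch count is at most
    ``max_mismatches`` and strictly better than the second best.  Masked N
    positions in the reference are wildcards (they match any read base).
    Ties and failures are logged.

    Returns
    -------
    (stacks, discards)
        ``stacks``: locus_id -> individual -> list of read sequences.
        ``discards``: list of (read_id, reason) with reasons
        ``"too_many_mismatches"`` or ``"multi_mapping"``.
    """
    retained = reference.retained
    if not retained:
        raise ValueError("reference is empty")
    width = max(len(l.representative) for l in retained)
    ref_mat = np.full((len(retained), width), _PAD_CEN, dtype=np.uint8)
    ref_len = np.zeros(len(retained), dtype=np.int64)
    for i, l in enumerate(retained):
        arr = seq_to_u8(l.representative)
        ref_mat[i, : arr.size] = arr
        ref_len[i] = arr.size
    ids = [l.locus_id for l in retained]
    ref_is_n = ref_mat == ord("N")

    stacks: dict = {l.locus_id: {} for l in retained}
    discards: list = []
    for ind, reads in reads_per_individual.items():
        for start in range(0, len(reads), chunk):
            batch = reads[start : start + chunk]
            probe = np.full((len(batch), width), _PAD_SEQ, dtype=np.uint8)
            rlen = np.zeros(len(batch), dtype=np.int64)
            for i, r in enumerate(batch):
                arr = seq_to_u8(r.sequence)[:width]
                probe[i, : arr.size] = arr
                rlen[i] = arr.size
            # mismatches over the overlap = overlap - matches
            real = probe != _PAD_SEQ
            matches = (
                (probe[:, None, :] == ref_mat[None, :, :])
                | (ref_is_n[None, :, :] & real[:, None, :])
            ).sum(axis=2)
            overlap = np.minimum(rlen[:, None], ref_len[None, :])
            mism = overlap - matches
            order = np.argsort(mism, axis=1)
            best = order[:, 0]
            best_m = mism[np.arange(len(batch)), best]
            second_m = (
                mism[np.arange(len(batch)), order[:, 1]]
                if len(retained) > 1
                else np.full(len(batch), np.iinfo(np.int64).max)
            )
            for i, r in enumerate(batch):
                if best_m[i] > max_mismatches:
                    discards.append((r.id, "too_many_mismatches"))
                elif best_m[i] == second_m[i]:
                    discards.append((r.id, "multi_mapping"))
                else:
                    stacks[ids[int(best[i])]].setdefault(ind, []).append(r.sequence)
    return stacks, discards
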