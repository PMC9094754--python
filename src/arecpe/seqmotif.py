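"""Sequence handling and ARE/CPE/PAS motif scanning for 3'-UTRs.

The AU-rich element (ARE) is the AUUUA pentamer; overlapping occurrences
are counted individually, so a maximal run ``A(TTTA)^k`` contributes
exactly ``k`` motifs.  The cytoplasmic polyadenylation element (CPE) is
represented by a seven-motif literal set (the canonical UUUUA(A)U family,
its A/C substitution variants, and the UUUUGU variant).  All scanning is
done on the sense strand of a canonical DNA-alphabet sequence; RNA input
is canonicalised with ``normalize_sequence`` (U -> T, uppercase).

Coordinates are 0-based, half-open throughout.  ``N`` characters never
participate in a match.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

ARE_MOTIF = "ATTTA"

#: The seven CPE literals scanned for occurrence counting.  At any shared
#: start offset at most one of these can match (pairwise start-exclusive),
#: so summing per-motif overlapping matches never double-counts.
CPE_MOTIFS: tuple[str, ...] = (
    "TTTTAT",
    "TTTTAAT",
    "TTTTAAAT",
    "TTTTACT",
    "TTTTCAT",
    "TTTTAAGT",
    "TTTTGT",
)

DEFAULT_PAS_MOTIFS: tuple[str, ...] = ("AATAAA", "ATTAAA")

#: Minimum number of AUUUA motifs for an mRNA to count as ARE-containing.
ARE_CONTAINING_MIN = 2

_VALID_ALPHABET = frozenset("ACGTN")
_BASES = "ACGT"


class InvalidAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N,U}."""


class MotifDesignError(RuntimeError):
    """Raised when a motif-editing or sequence-design constraint cannot be met."""


@dataclass(frozen=True)
class UTRRecord:
    """One gene/transcript 3'-UTR sequence in the canonical DNA alphabet."""

    gene_id: str
    sequence: str
    transcript_id: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifMatch:
    """A literal motif occurrence; ``end`` is exclusive."""

    motif: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif):
            raise ValueError("end - start must equal motif length")


@dataclass
class MotifCounts:
    """Per-gene ARE/CPE content of one (longest) 3'-UTR."""

    gene_id: str
    n_are: int
    n_cpe: int
    cpe_positional: bool
    utr_length: int
    transcript_id: str | None = None


@dataclass
class PositionalConfig:
    """Parameters for the PAS-distance-aware CPE call.

    A CPE only counts when its start lies within ``max_distance_nt``
    upstream of a polyadenylation-signal (PAS) hexamer start.  The exact
    optimal windows come from prior CPE-predictor work and are not fixed
    here; the 100-nt default is a documented, configurable choice.
    """

    pas_motifs: tuple[str, ...] = DEFAULT_PAS_MOTIFS
    max_distance_nt: int = 100
    require_pas: bool = True

    def __post_init__(self) -> None:
        if not self.pas_motifs:
            raise ValueError("pas_motifs must be non-empty")
        if self.max_distance_nt <= 0:
            raise ValueError("max_distance_nt must be positive")


def normalize_sequence(raw: str) -> str:
    """Canonicalise a nucleotide string: uppercase, U -> T, validate alphabet.

    Raises :class:`InvalidAlphabetError` naming the first offending position.
    Idempotent on already-canonical sequences.
    """
    if not raw:
        raise InvalidAlphabetError("empty sequence")
    seq = raw.upper().replace("U", "T")
    if not set(seq) <= _VALID_ALPHABET:
        for i, ch in enumerate(seq):
            if ch not in _VALID_ALPHABET:
                raise InvalidAlphabetError(
                    f"invalid character {ch!r} at position {i}"
                )
    return seq


def find_overlapping(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) start offsets of ``motif`` in ``seq``."""
    starts: list[int] = []
    i = seq.find(motif)
    while i != -1:
        starts.append(i)
        i = seq.find(motif, i + 1)
    return starts


def count_are(seq: str) -> int:
    """Number of overlapping AUUUA starts; a run ``A(TTTA)^k`` counts k."""
    return len(find_overlapping(seq, ARE_MOTIF))


def find_cpe_matches(seq: str) -> list[MotifMatch]:
    """All occurrences of the seven CPE motifs, sorted by start offset."""
    matches = [
        MotifMatch(motif, s, s + len(motif))
        for motif in CPE_MOTIFS
        for s in find_overlapping(seq, motif)
    ]
    matches.sort(key=lambda m: m.start)
    return matches


def count_cpe(seq: str) -> int:
    """Plain occurrence count over the seven CPE motifs (no PAS-distance rule)."""
    return len(find_cpe_matches(seq))


def find_pas(seq: str, cfg: PositionalConfig | None = None) -> list[MotifMatch]:
    """All occurrences of the configured PAS hexamers, sorted by start."""
    cfg = cfg or PositionalConfig()
    matches = [
        MotifMatch(motif, s, s + len(motif))
        for motif in cfg.pas_motifs
        for s in find_overlapping(seq, motif)
    ]
    matches.sort(key=lambda m: m.start)
    return matches


def classify_cpe_positional(
    seq: str, cfg: PositionalConfig | None = None
) -> tuple[bool, str]:
    """PAS-distance-aware CPE-containing call.

    Returns ``(flag, reason)``.  ``flag`` is True iff some CPE match starts
    within ``cfg.max_distance_nt`` nucleotides upstream of a PAS start.
    With ``require_pas`` and no PAS in the sequence the call is False.
    """
    cfg = cfg or PositionalConfig()
    cpes = find_cpe_matches(seq)
    if not cpes:
        return False, "no CPE motif in sequence"
    pas = find_pas(seq, cfg)
    if not pas:
        if cfg.require_pas:
            return False, "no PAS found (require_pas=True)"
        return True, f"{len(cpes)} CPE(s); no PAS required"
    for cpe in cpes:
        for p in pas:
            gap = p.start - cpe.start
            if 0 <= gap <= cfg.max_distance_nt:
                return True, (
                    f"{cpe.motif} at {cpe.start} is {gap} nt upstream of "
                    f"{p.motif} at {p.start} (window {cfg.max_distance_nt})"
                )
    return False, (
        f"{len(cpes)} CPE(s) present but none within "
        f"{cfg.max_distance_nt} nt upstream of a PAS"
    )


def is_are_containing(n_are: int) -> bool:
    """True iff the UTR carries two or more AUUUA motifs."""
    if n_are < 0:
        raise ValueError("n_are must be non-negative")
    return n_are >= ARE_CONTAINING_MIN


def _all_regulatory_starts(seq: str) -> set[tuple[str, int]]:
    """(motif, start) pairs for every ARE and CPE occurrence in ``seq``."""
    out = {(ARE_MOTIF, s) for s in find_overlapping(seq, ARE_MOTIF)}
    out.update((m.motif, m.start) for m in find_cpe_matches(seq))
    return out


def inactivate_motifs(
    rec: UTRRecord,
    targets: Sequence[MotifMatch],
    seed: int,
    max_tries: int = 200,
) -> UTRRecord:
    """Point-mutate the targeted matches so they no longer match any ARE/CPE.

    Emulates reporter-construct mutagenesis (e.g. TTTTAAT -> TTgggAT): the
    sequence keeps its length, every targeted match is destroyed, and the
    edit is rejected and resampled if it would create a new ARE or CPE
    match anywhere in the sequence.  Deterministic given ``seed``.
    """
    seq = rec.sequence
    for t in targets:
        if seq[t.start:t.end] != t.motif:
            raise ValueError(
                f"target {t.motif} at {t.start} not present in sequence"
            )
    if not targets:
        return rec

    rng = random.Random(seed)
    target_keys = {(t.motif, t.start) for t in targets}
    allowed = _all_regulatory_starts(seq) - target_keys
    pending = set(target_keys)

    chars = list(seq)
    for t in sorted(targets, key=lambda m: m.start):
        pending.discard((t.motif, t.start))
        acceptable = allowed | pending  # targets not yet edited may remain
        original = chars[t.start:t.end]
        done = False
        for _ in range(max_tries):
            chars[t.start:t.end] = original
            # mutate 2-3 internal positions, mirroring the published edits
            k = rng.choice((2, 3))
            positions = rng.sample(range(t.start, t.end), k)
            for pos in positions:
                chars[pos] = rng.choice([b for b in _BASES if b != chars[pos]])
            candidate = "".join(chars)
            now = _all_regulatory_starts(candidate)
            if now <= acceptable:
                done = True
                break
        if not done:
            chars[t.start:t.end] = original
            raise MotifDesignError(
                f"could not inactivate {t.motif} at {t.start} within "
                f"{max_tries} attempts without creating new motifs"
            )
    return replace(rec, sequence="".join(chars))


def select_longest_utr(records: Iterable[UTRRecord]) -> list[UTRRecord]:
    """One record per gene: the longest 3'-UTR, ties broken by transcript id.

    Returns records sorted by gene_id.  Raises on empty input.
    """
    by_gene: dict[str, list[UTRRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)
    if not by_gene:
        raise ValueError("no UTR records supplied")
    chosen = []
    for gene_id in sorted(by_gene):
        group = by_gene[gene_id]
        group.sort(key=lambda r: (-r.length, r.transcript_id or ""))
        chosen.append(group[0])
    return chosen


def scan_record(
    rec: UTRRecord, positional_cfg: PositionalConfig | None = None
) -> MotifCounts:
    """ARE/CPE counts and the positional-CPE flag for one UTR."""
    flag, _ = classify_cpe_positional(rec.sequence, positional_cfg)
    return MotifCounts(
        gene_id=rec.gene_id,
        n_are=count_are(rec.sequence),
        n_cpe=count_cpe(rec.sequence),
        cpe_positional=flag,
        utr_length=rec.length,
        transcript_id=rec.transcript_id,
    )


def scan_records(
    records: Iterable[UTRRecord],
    positional_cfg: PositionalConfig | None = None,
    longest_per_gene: bool = True,
) -> list[MotifCounts]:
    """Scan a collection of UTRs, optionally reducing to one isoform per gene."""
    recs = list(records)
    if longest_per_gene:
        recs = select_longest_utr(recs)
    return [scan_record(r, positional_cfg) for r in recs]
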