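"""Read-level quality rules: Q20 masking and length / N-fraction filtering.

The rules operate on already-sequenced reads: bases below a Phred quality
threshold are masked to ``N``; reads that end up too short or too N-rich are
discarded.  Paired-end synchronisation is a thin layer on top: by default a
pair is dropped when either mate fails.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class ReadRecord:
    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but {len(self.quals)} quals"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id}: negative quality score")


def mask_low_quality(read: ReadRecord, q_min: int = 20) -> ReadRecord:
    """Replace every base with Phred quality < ``q_min`` by ``N``.

    The threshold is strict: a base at exactly ``q_min`` is kept.  Length and
    qualities are preserved, so masking is idempotent.
    """
    bases = "".join(
        "N" if q < q_min else b for b, q in zip(read.bases, read.quals)
    )
    return ReadRecord(id=read.id, bases=bases, quals=list(read.quals))


def filter_read(read: ReadRecord, min_len: int = 90, max_n_frac: float = 0.10) -> bool:
    """Keep/discard decision after masking.

    A read is discarded iff it is shorter than ``min_len`` bases or the
    fraction of ``N`` calls strictly exceeds ``max_n_frac``.  Returns True to
    keep.  Boundary cases (exactly ``min_len`` bp, exactly ``max_n_frac`` Ns)
    are kept.
    """
    n = len(read.bases)
    if n < min_len:
        return False
    n_frac = read.bases.upper().count("N") / n
    return n_frac <= max_n_frac


def filter_pairs(
    pairs: list[tuple[ReadRecord, ReadRecord]],
    q_min: int = 20,
    min_len: int = 90,
    max_n_frac: float = 0.10,
    drop_pairwise: bool = True,
) -> list[tuple[ReadRecord | None, ReadRecord | None]]:
    """Mask and filter read pairs.

    With ``drop_pairwise`` (default) a pair survives only if both mates pass;
    otherwise surviving singletons are returned with the failed mate as None.
    """
    out: list[tuple[ReadRecord | None, ReadRecord | None]] = []
    for r1, r2 in pairs:
        m1, m2 = mask_low_quality(r1, q_min), mask_low_quality(r2, q_min)
        k1, k2 = (
            filter_read(m1, min_len, max_n_frac),
            filter_read(m2, min_len, max_n_frac),
        )
        if drop_pairwise:
            if k1 and k2:
                out.append((m1, m2))
        elif k1 or k2:
            out.append((m1 if k1 else None, m2 if k2 else None))
    return out
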