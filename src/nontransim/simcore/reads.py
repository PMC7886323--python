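"""Amplicon FASTQ emission at a configured variant frequency.

Fixture generator for the read-counting quantification: reads are drawn
from the ancestral or derived template with probability (1 - f, f), with
random start positions guaranteed to cover the variant's flanked window,
independent per-base substitution errors, and about half the reads emitted
as reverse complements.  Qualities are written Phred+33.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..seqstats import Variant

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def apply_variant(reference: str, variant: Variant) -> str:
    """The derived template: reference with the variant applied."""
    p = variant.position
    if reference[p : p + len(variant.ref)] != variant.ref:
        raise ValueError("variant ref does not match the reference sequence")
    return reference[:p] + variant.alt + reference[p + len(variant.ref) :]


def emit_amplicon_reads(
    reference: str,
    variant: Variant,
    true_freq: float,
    depth: int,
    read_length: int = 100,
    error_rate: float = 0.001,
    seed: int = 0,
    flank: int = 5,
) -> list[SeqRecord]:
    """Emit ``depth`` reads covering the variant site with its flanks."""
    if not (0.0 <= true_freq <= 1.0):
        raise ValueError("true_freq must be in [0, 1]")
    if not (0 <= variant.position < len(reference)):
        raise ValueError("variant position outside reference")
    span = 2 * flank + max(len(variant.ref), len(variant.alt))
    if read_length < span:
        raise ValueError(
            f"read_length {read_length} shorter than the {span} nt probe span"
        )
    rng = np.random.default_rng(seed)
    derived = apply_variant(reference, variant)
    templates = (reference, derived)
    reads = []
    for i in range(depth):
        is_derived = rng.random() < true_freq
        template = templates[1] if is_derived else templates[0]
        # window that must be covered (in this template's coordinates)
        w_start = max(0, variant.position - flank)
        w_end = min(
            len(template),
            variant.position + (len(variant.alt) if is_derived else len(variant.ref)) + flank,
        )
        lo = max(0, w_end - read_length)
        hi = min(w_start, len(template) - read_length)
        start = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        seq = template[start : start + read_length]
        if error_rate > 0:
            arr = list(seq)
            errs = np.nonzero(rng.random(len(arr)) < error_rate)[0]
            for j in errs:
                arr[j] = rng.choice([b for b in "ACGT" if b != arr[j]])
            seq = "".join(arr)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        qual = [int(q) for q in rng.integers(30, 41, size=len(seq))]
        rec = SeqRecord(Seq(seq), id=f"read{i}", description="")
        rec.letter_annotations["phred_quality"] = qual
        reads.append(rec)
    return reads
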