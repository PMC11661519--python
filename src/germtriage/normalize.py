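"""Variant normalization: trimming and left-alignment against a reference window.

Implements the standard minimal-representation algorithm (as used by
``vt normalize`` and ``bcftools norm``): shared suffix bases are trimmed,
indels are shifted left through repeat context as far as the window
allows, and shared prefix bases beyond a single anchor are trimmed.
Needed so that variants described at different anchor points (HGVS g.
descriptions vs. VCF records) compare equal on the join key.
"""

from __future__ import annotations

from .models import GenomicVariant, ReferenceWindow, infer_variant_class


class ReferenceMismatchError(ValueError):
    """The variant's ref allele disagrees with the supplied reference window."""


def normalize_variant(v: GenomicVariant, window: ReferenceWindow) -> GenomicVariant:
    """Return the left-aligned, minimal representation of ``v``.

    Idempotent and position-monotone (the result never lies right of the
    input). Raises :class:`ReferenceMismatchError` when the ref allele
    does not match ``window`` and ``IndexError`` when the window does not
    cover the locus.
    """
    if window.chrom != v.chrom:
        raise ReferenceMismatchError(
            f"window on {window.chrom} cannot normalize variant on {v.chrom}"
        )
    observed = window.slice(v.pos, v.end)
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"ref allele {v.ref!r} at {v.chrom}:{v.pos} does not match "
            f"reference {observed!r}"
        )

    pos, ref, alt = v.pos, v.ref, v.alt
    while True:
        changed = False
        # Trim a shared terminal base; if either allele would empty,
        # extend both to the left with the preceding reference base.
        if ref[-1] == alt[-1]:
            if len(ref) == 1 or len(alt) == 1:
                if pos <= window.start:
                    break  # cannot extend further left
                pos -= 1
                b = window.base_at(pos)
                ref, alt = b + ref, b + alt
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        # Trim shared leading bases down to a single anchor.
        if len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
            changed = True
        if not changed:
            break
    return GenomicVariant(v.chrom, pos, ref, alt, infer_variant_class(ref, alt))
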