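"""Allelic-discrimination analysis of pathogenic variants against PAM sets.

A PAM placement discriminates a variant when it matches the mutated allele,
its footprint overlaps the mutated bases, and the corresponding placement
fails on the wild-type allele. Both strands are tested by reverse
complementing the context windows. A PAM matching both alleles is never
counted, even when it overlaps the variant: allelic discrimination demands
that the wild type escape.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from ._sequences import iupac_matches, revcomp
from .model import TargetabilityResult, VariantRecord


def apply_variant(window: str, offset: int, ref: str, alt: str) -> str:
    """Replace ``ref`` with ``alt`` at ``offset`` of the window."""
    if window[offset : offset + len(ref)] != ref:
        raise ValueError(
            f"ref {ref!r} not found at offset {offset} "
            f"(window has {window[offset:offset + len(ref)]!r})"
        )
    return window[:offset] + alt + window[offset + len(ref) :]


def iupac_match(pam: str, sequence: str, offset: int) -> bool:
    """True iff the IUPAC PAM matches the sequence at the given offset."""
    if offset < 0 or offset + len(pam) > len(sequence):
        raise ValueError("placement outside sequence")
    return iupac_matches(pam, sequence[offset : offset + len(pam)])


def _matching_offsets(pam: str, seq: str) -> set[int]:
    return {o for o in range(len(seq) - len(pam) + 1) if iupac_matches(pam, seq[o : o + len(pam)])}


def _overlaps(o: int, length: int, span: tuple[int, int]) -> bool:
    # zero-length spans (pure deletions) follow the junction convention:
    # s == e, and a footprint overlaps when it straddles the junction
    s, e = span
    return o < e and o + length > s if s < e else o < s < o + length


def allelic_discrimination(
    pams: Iterable[str],
    wt_window: str,
    mut_window: str,
    mut_span: tuple[int, int],
    wt_span: tuple[int, int] | None = None,
    variant_id: str = "",
    inheritance: str = "",
    require_wt_mismatch: bool = True,
) -> TargetabilityResult:
    """Decide whether any PAM placement separates the mutated allele.

    ``mut_span`` is the half-open coordinate range of the mutated bases in
    the mutated window; ``wt_span`` the range of the reference bases in the
    wild-type window (defaults to ``mut_span``, correct for substitutions).
    For length-changing variants, placements are enumerated independently on
    each allele: discrimination requires a matching placement overlapping
    the variant on the mutated allele and no matching wild-type placement
    whose footprint overlaps the variant locus.

    With ``require_wt_mismatch=False`` only the overlap condition is
    applied (the looser, coverage-style reading).
    """
    wt_span = mut_span if wt_span is None else wt_span
    discriminating: list[tuple[str, str, int]] = []
    for pam in pams:
        for strand in ("+", "-"):
            if strand == "+":
                mut_seq, wt_seq = mut_window, wt_window
                m_span, w_span = mut_span, wt_span
            else:
                mut_seq, wt_seq = revcomp(mut_window), revcomp(wt_window)
                m_span = (len(mut_window) - mut_span[1], len(mut_window) - mut_span[0])
                w_span = (len(wt_window) - wt_span[1], len(wt_window) - wt_span[0])
            mut_hits = [
                o for o in sorted(_matching_offsets(pam, mut_seq))
                if _overlaps(o, len(pam), m_span)
            ]
            if not mut_hits:
                continue
            if require_wt_mismatch:
                wt_hits = [
                    o for o in _matching_offsets(pam, wt_seq)
                    if _overlaps(o, len(pam), w_span)
                ]
                if len(mut_window) == len(wt_window):
                    # coordinates are pairable: require the same placement to fail
                    mut_hits = [o for o in mut_hits if o not in set(wt_hits)]
                elif wt_hits:
                    # indel: any overlapping wild-type match defeats discrimination
                    mut_hits = []
            for o in mut_hits:
                discriminating.append((pam, strand, o))
    return TargetabilityResult(
        variant_id=variant_id,
        targetable=bool(discriminating),
        discriminating_pams=discriminating,
        inheritance=inheritance,
    )


def assess_variant(
    variant: VariantRecord, pams: Sequence[str], require_wt_mismatch: bool = True
) -> TargetabilityResult:
    """Run allelic discrimination for one VariantRecord."""
    mut_window = apply_variant(variant.window_seq, variant.window_offset, variant.ref, variant.alt)
    mut_span = (variant.window_offset, variant.window_offset + len(variant.alt))
    wt_span = (variant.window_offset, variant.window_offset + len(variant.ref))
    return allelic_discrimination(
        pams,
        wt_window=variant.window_seq,
        mut_window=mut_window,
        mut_span=mut_span,
        wt_span=wt_span,
        variant_id=variant.variant_id,
        inheritance=variant.inheritance,
        require_wt_mismatch=require_wt_mismatch,
    )


def aggregate_by_inheritance(results: Sequence[TargetabilityResult]) -> pd.DataFrame:
    """Targetable fraction per mode of inheritance, plus an overall row.

    Fractions are computed with exact rational arithmetic before being
    rendered as floats.
    """
    if not results:
        return pd.DataFrame(columns=["inheritance", "n_total", "n_targetable", "fraction"])
    rows = []
    modes = sorted({r.inheritance for r in results})
    for mode in modes + ["(all)"]:
        subset = results if mode == "(all)" else [r for r in results if r.inheritance == mode]
        n_hit = sum(1 for r in subset if r.targetable)
        frac = Fraction(n_hit, len(subset))
        rows.append(
            {
                "inheritance": mode,
                "n_total": len(subset),
                "n_targetable": n_hit,
                "fraction": float(frac),
            }
        )
    return pd.DataFrame(rows)
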