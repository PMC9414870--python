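"""QTL naming in gene-symbol-catalog style: Q.<trait>-<chromosome>.

The first QTL of a (trait, chromosome) pair keeps the bare name, e.g.
``Q.sA-3A``; further QTLs of the same pair get ordinal suffixes in
peak-position order, e.g. ``Q.sA-2B.2``.
"""

from __future__ import annotations

__all__ = ["name_qtl"]


def name_qtl(trait: str, chrom: str, existing_names: set[str]) -> str:
    """Allocate the next free name for (trait, chrom) and register it."""
    base = f"Q.{trait}-{chrom}"
    if base not in existing_names:
        existing_names.add(base)
        return base
    k = 2
    while f"{base}.{k}" in existing_names:
        k += 1
    name = f"{base}.{k}"
    existing_names.add(name)
    return name
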