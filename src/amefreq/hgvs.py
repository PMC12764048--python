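"""Shallow HGVS pattern rules for assigning a consequence class.

This is deliberately not a full HGVS grammar: the pipeline only needs the
coarse consequence class (missense / nonsense / frameshift / in-frame
indel / splice site), and curated allele-count tables describe variants
with simple ``p.``/``c.`` strings.  The rules:

* ``fs`` anywhere in the protein change  -> frameshift
* simple substitution ending in ``Ter``  -> nonsense
* ``delins`` / ``del`` / ``dup`` / ``ins`` without ``fs`` -> in-frame indel
* simple one-residue substitution        -> missense
* no protein change and a cDNA position with an intronic offset
  (``c.665-1G>A``, ``c.123+2T>C``)       -> splice site
* anything else                          -> other
"""

from __future__ import annotations

import re
from typing import Optional

from .schema import Consequence

_AA = r"(?:[A-Z][a-z]{2}|\*|X)"
_SUBST_TER = re.compile(rf"^p\.\(?{_AA}\d+(?:Ter|\*)\)?$")
_SUBST_MISSENSE = re.compile(rf"^p\.\(?{_AA}\d+{_AA}\)?$")
_INDEL = re.compile(r"delins|del|dup|ins")
# an intronic offset looks like "665-1" or "123+2" inside the c. description
_INTRONIC_OFFSET = re.compile(r"\d+[+-]\d+")


def infer_consequence(
    protein_change: Optional[str], cdna_change: Optional[str]
) -> Consequence:
    """Infer the consequence class from HGVS-style change strings.

    At least one of the two must be provided.  Used when an input table
    has no explicit consequence column.
    """
    if not protein_change and not cdna_change:
        raise ValueError("need a protein change or a cDNA change to infer consequence")

    if protein_change:
        p = protein_change.strip()
        if "fs" in p:
            return Consequence.FRAMESHIFT
        if _SUBST_TER.match(p):
            return Consequence.NONSENSE
        if _INDEL.search(p):
            return Consequence.INFRAME_INDEL
        if _SUBST_MISSENSE.match(p):
            return Consequence.MISSENSE
        return Consequence.OTHER

    c = (cdna_change or "").strip()
    if _INTRONIC_OFFSET.search(c):
        return Consequence.SPLICE_SITE
    return Consequence.OTHER
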