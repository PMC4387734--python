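"""Marker-type detection and annotation URL construction.

Identifiers are classified as dbSNP rsIDs, Ensembl IDs, gene symbols,
or unknown, and mapped to NCBI / DAVID lookup URLs.  No network access
happens anywhere in this package: URLs are only constructed so callers
(CLI, HTML reports) can print or embed them.

Ensembl IDs are recognized but deliberately not linked: web annotation
for them is unsupported in this version.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "MarkerType",
    "URL_TEMPLATES",
    "detect_marker_type",
    "annotation_url",
]

_RSID_RE = re.compile(r"^rs\d+$", re.IGNORECASE)
_ENSEMBL_RE = re.compile(r"^ENS[A-Z]*[GTP]\d+$")

#: URL templates by (marker kind, target).  Kept in one place so they can
#: be updated when the destination sites change their schemes.
URL_TEMPLATES: dict[tuple[str, str], str] = {
    ("snp_rsid", "ncbi"): "https://www.ncbi.nlm.nih.gov/snp/{id}",
    ("gene_symbol", "ncbi"): "https://www.ncbi.nlm.nih.gov/gene/?term={id}",
    ("gene_symbol", "david"): (
        "https://david.ncifcrf.gov/api.jsp?type=OFFICIAL_GENE_SYMBOL&ids={id}&tool=summary"
    ),
}


@dataclass(frozen=True)
class MarkerType:
    """Detected identifier class: snp_rsid, gene_symbol, ensembl_id, or unknown."""

    kind: str

    KINDS = ("snp_rsid", "gene_symbol", "ensembl_id", "unknown")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"invalid marker kind {self.kind!r}")


def detect_marker_type(marker_id: str) -> MarkerType:
    """Classify a marker identifier by its shape.

    ``rs`` + digits (case-insensitive) is an rsID; ``ENS...[GTP]`` +
    digits is an Ensembl ID; other purely alphanumeric ids are taken as
    gene symbols (probe ids fall here too — they are indistinguishable
    from symbols by shape); anything else is unknown.
    """
    if not marker_id:
        raise ValueError("marker id must be non-empty")
    if _RSID_RE.match(marker_id):
        return MarkerType("snp_rsid")
    if _ENSEMBL_RE.match(marker_id):
        return MarkerType("ensembl_id")
    if marker_id.isalnum():
        return MarkerType("gene_symbol")
    return MarkerType("unknown")


def annotation_url(marker_id: str, target: str = "ncbi") -> str | None:
    """Annotation URL for a marker, or None when unsupported.

    rsIDs link to the dbSNP record page (NCBI only); gene symbols link
    to an NCBI Gene search or a DAVID gene lookup; Ensembl IDs and
    unknown identifiers yield None.
    """
    if target not in {"ncbi", "david"}:
        raise ValueError(f"target must be 'ncbi' or 'david', got {target!r}")
    kind = detect_marker_type(marker_id).kind
    template = URL_TEMPLATES.get((kind, target))
    if template is None:
        return None
    return template.format(id=marker_id)
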