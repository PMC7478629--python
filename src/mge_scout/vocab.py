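"""Controlled domain-tag vocabulary and the bundled ESX signature table.

The pipeline never matches free-text products directly: loaders (or the
helper :func:`tags_from_product`) map annotation text onto this controlled
vocabulary once, and every downstream rule matches tags only.
"""
from __future__ import annotations

import re

# ---------------------------------------------------------------------------
# Domain tags

#: T7SS core components (locus calling operates on these only).
ESX_CORE_TAGS = ("EccA", "EccB", "EccC", "EccD", "EccE", "MycP")

#: Backbone/feature tags used by the element classifier.
BACKBONE_TAGS = (
    "RepA",
    "Relaxase",
    "VirD4",
    "VirB4",
    "TcpC",
    "DnaB",          # replicative DNA helicase (DnaB-like)
    "PolI",          # DNA polymerase I
    "Integrase",
    "Transposase",   # DDE-transposase / IS element
    "tRNA",
    "Toxin",         # TA-system toxin
    "Antitoxin",     # TA-system antitoxin
)

CONTROLLED_TAGS = frozenset(ESX_CORE_TAGS) | frozenset(BACKBONE_TAGS)

#: Accepted spellings for each tag (case-insensitive exact synonyms).
TAG_SYNONYMS: dict[str, str] = {
    "ecca": "EccA",
    "ftsk/spoiiie-atpase-t7": "EccA",
    "eccb": "EccB",
    "eccc": "EccC",
    "eccd": "EccD",
    "ecce": "EccE",
    "mycp": "MycP",
    "mycosin": "MycP",
    "mycosin-protease": "MycP",
    "repa": "RepA",
    "relaxase": "Relaxase",
    "mob-relaxase": "Relaxase",
    "mob": "Relaxase",
    "vird4": "VirD4",
    "vird4/t4cp": "VirD4",
    "t4cp": "VirD4",
    "virb4": "VirB4",
    "tcpc": "TcpC",
    "tcpc/virb8-like": "TcpC",
    "virb8": "TcpC",
    "dnab": "DnaB",
    "dnab-helicase": "DnaB",
    "helicase": "DnaB",
    "poli": "PolI",
    "dna-poli": "PolI",
    "dna_polymerase": "PolI",
    "integrase": "Integrase",
    "transposase": "Transposase",
    "dde-transposase": "Transposase",
    "dde-transposase/is": "Transposase",
    "is": "Transposase",
    "trna": "tRNA",
    "toxin": "Toxin",
    "ta-toxin": "Toxin",
    "antitoxin": "Antitoxin",
    "ta-antitoxin": "Antitoxin",
}


def normalize_tag(raw: str) -> str | None:
    """Map a raw tag spelling onto the controlled vocabulary.

    Returns the canonical tag, or None if the spelling is unknown.
    """
    raw = raw.strip()
    if not raw:
        return None
    if raw in CONTROLLED_TAGS:
        return raw
    return TAG_SYNONYMS.get(raw.lower())


# Keyword patterns (searched, not matched exactly) for deriving tags from
# free-text product strings of Prokka-style annotations.
_PRODUCT_PATTERNS: tuple[tuple[str, str], ...] = (
    (r"\becca\b|ftsk/spoiiie.*(t7|esx)", "EccA"),
    (r"\beccb\b", "EccB"),
    (r"\beccc\b", "EccC"),
    (r"\beccd\b", "EccD"),
    (r"\becce\b", "EccE"),
    (r"\bmycp\b|mycosin", "MycP"),
    (r"\brepa\b|replication initiat", "RepA"),
    (r"relaxase|mobilization protein mob", "Relaxase"),
    (r"\bvird4\b|coupling protein|\bt4cp\b", "VirD4"),
    (r"\bvirb4\b", "VirB4"),
    (r"\btcpc\b|virb8", "TcpC"),
    (r"\bdnab\b|replicative dna helicase", "DnaB"),
    (r"dna polymerase i\b", "PolI"),
    (r"integrase", "Integrase"),
    (r"transposase|\bis\d+\b|insertion sequence", "Transposase"),
    (r"\btrna\b", "tRNA"),
    (r"antitoxin", "Antitoxin"),
    (r"(?<!anti)toxin\b", "Toxin"),
)


def tags_from_product(product: str) -> frozenset[str]:
    """Derive controlled tags from a free-text product label.

    A convenience for annotations that lack explicit domain tags; keyword
    based and deliberately conservative — explicit tags always win.
    """
    text = product.lower()
    found = {tag for pat, tag in _PRODUCT_PATTERNS if re.search(pat, text)}
    # "antitoxin" contains "toxin"; the lookbehind above handles the common
    # case, but a product naming both halves keeps both tags, which is right.
    return frozenset(found)


# ---------------------------------------------------------------------------
# ESX reference signatures

#: Reference gene-order signatures for ESX (T7SS) locus typing.  Signatures
#: use lowercase gene-name tokens joined by "/" with "-//-" marking a distal
#: eccA.  Provenance: "observed" entries reproduce orders reported for
#: mycobacterial mobile elements; "canonical" entries are the standard
#: chromosomal locus orders from the T7SS literature.  Users may extend the
#: table passed to classify_esx_type.
ESX_REFERENCE_SIGNATURES: dict[str, str] = {
    # observed on mobile elements
    "ESX-4-bis": "eccE/eccB/eccD/eccC/eccD/mycP/-//-/eccA",
    "ESX-2-like": "eccC/eccB/eccD/mycP/eccE/-//-/eccA",
    # canonical chromosomal orders (eccC split in two genes in ESX-1)
    "ESX-1": "eccA/eccB/eccC/eccC/eccD/mycP/eccE",
    "ESX-3-like": "eccA/eccB/eccC/eccD/mycP/eccE",
    "ESX-4": "eccB/eccC/mycP/eccD/eccE",
}

#: Display form of core-gene tokens used in signatures.
TAG_TO_GENE = {
    "EccA": "eccA",
    "EccB": "eccB",
    "EccC": "eccC",
    "EccD": "eccD",
    "EccE": "eccE",
    "MycP": "mycP",
}
GENE_TO_TAG = {v: k for k, v in TAG_TO_GENE.items()}

GAP_MARK = "-//-"
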