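"""Viral marker-gene flagging by keyword lexicon.

Gene product strings are tokenized on non-alphanumeric characters and
matched case-insensitively against a lexicon of viral terms. Two term
forms carry wildcards: ``phage`` and ``virus`` match as token suffixes
(so "bacteriophage" and "myovirus" fire), and terms written with a
trailing ``*`` (``podo*``, ``myovir*``, ``siphovir*``) match token
prefixes. Everything else must match a whole token, which keeps short
terms like "head", "mu" and "t4" from firing inside longer words.

Integrase and transposase are excluded: both occur in bacterial genomes
unrelated to phages. An exclusion cancels only its own match — a product
like "phage integrase" is still phage-flagged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .model import GeneAnnotation

DEFAULT_KEYWORDS: tuple[str, ...] = (
    "phage", "virus", "virion", "prophage", "terminase", "capsid", "head",
    "tail", "fiber", "baseplate", "portal", "lysis", "structural", "t4",
    "lambda", "mu", "lambdoid", "podo*", "myovir*", "siphovir*",
)
DEFAULT_EXCLUSIONS: tuple[str, ...] = ("integrase", "transposase")

# phage/virus behave as suffix wildcards (the lexicon's *phage / *virus forms)
_SUFFIX_TERMS = frozenset({"phage", "virus"})

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


@dataclass(frozen=True)
class MarkerLexicon:
    """Keyword lexicon with exclusions. Terms are lowercase; a trailing
    ``*`` marks prefix-wildcard terms."""

    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS

    def __post_init__(self) -> None:
        object.__setattr__(self, "keywords", tuple(k.lower() for k in self.keywords))
        object.__setattr__(self, "exclusions", tuple(e.lower() for e in self.exclusions))


@dataclass(frozen=True)
class MarkerHit:
    annotation: GeneAnnotation
    matched_keywords: frozenset[str]

    def __post_init__(self) -> None:
        if not self.matched_keywords:
            raise ValueError("MarkerHit requires at least one matched keyword")


def _tokenize(text: str) -> list[str]:
    return [t for t in _TOKEN_RE.split(text.lower()) if t]


def match_viral_keywords(product_text: str, lexicon: MarkerLexicon | None = None) -> set[str]:
    """Return the lexicon keywords matched by any token of a product string.

    Exclusion terms never match as keywords themselves but do not veto
    other matches in the same product.
    """
    lex = lexicon or MarkerLexicon()
    exclusions = set(lex.exclusions)
    matched: set[str] = set()
    for token in _tokenize(product_text):
        if token in exclusions:
            continue
        for kw in lex.keywords:
            if kw in matched:
                continue
            if kw.endswith("*"):
                if token.startswith(kw[:-1]):
                    matched.add(kw)
            elif kw in _SUFFIX_TERMS:
                if token.endswith(kw):
                    matched.add(kw)
            elif token == kw:
                matched.add(kw)
    return matched


def scan_annotations(
    annotations: list[GeneAnnotation], lexicon: MarkerLexicon | None = None
) -> list[MarkerHit]:
    """One MarkerHit per gene whose product matches ≥1 keyword.

    tRNA features never produce hits; output order follows input order.
    """
    lex = lexicon or MarkerLexicon()
    hits: list[MarkerHit] = []
    for ann in annotations:
        if ann.feature_kind != "gene":
            continue
        matched = match_viral_keywords(ann.product, lex)
        if matched:
            hits.append(MarkerHit(ann, frozenset(matched)))
    return hits


def write_marker_hits(hits: list[MarkerHit], tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("contig_id\tstart\tend\tgene_id\tmatched_keywords\n")
        for h in hits:
            a = h.annotation
            fh.write(
                f"{a.contig_id}\t{a.start}\t{a.end}\t{a.gene_id}\t"
                f"{','.join(sorted(h.matched_keywords))}\n"
            )
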