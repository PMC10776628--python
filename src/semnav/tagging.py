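"""Pluggable lemmatization/POS tagging.

Feature extraction needs lemmatized content words.  Production users
plug in a real morphological tagger (any callable mapping a surface
token to ``(lemma, pos)`` or ``None``); transcripts may also ship
pre-tagged ``lemma_seq``/``pos_seq`` columns, which bypass tagging
entirely.  For tests and demos this module provides a lookup tagger
backed by an explicit dictionary, plus a small built-in Spanish demo
dictionary covering common property-listing vocabulary.
"""

from __future__ import annotations

from typing import Mapping, Optional

from semnav.ingest import casefold_lemma

#: Spanish function words returned as None (dropped from content analysis).
SPANISH_FUNCTION_WORDS = frozenset(
    """
    el la los las un una unos unas de del a al en con por para sin sobre
    y o u e ni que se su sus le les lo mi mis tu tus es son esta este esto
    estos estas ese esa eso esos esas aquel aquella hay muy mas más pero
    cuando como donde si no
    """.split()
)

#: surface -> (lemma, pos) demo dictionary (coarse universal-style tags).
SPANISH_DEMO_LEXICON: dict[str, tuple[str, str]] = {
    "tiene": ("tener", "verb"),
    "tienen": ("tener", "verb"),
    "alas": ("ala", "noun"),
    "ala": ("ala", "noun"),
    "vuela": ("volar", "verb"),
    "vuelan": ("volar", "verb"),
    "amarillo": ("amarillo", "adjective"),
    "amarilla": ("amarillo", "adjective"),
    "caliente": ("caliente", "adjective"),
    "grande": ("grande", "adjective"),
    "plumas": ("pluma", "noun"),
    "pluma": ("pluma", "noun"),
    "rápido": ("rápido", "adjective"),
    "rápidamente": ("rápidamente", "adverb"),
    "brilla": ("brillar", "verb"),
    "calor": ("calor", "noun"),
    "luz": ("luz", "noun"),
    "agua": ("agua", "noun"),
    "nada": ("nadar", "verb"),
    "hojas": ("hoja", "noun"),
    "verde": ("verde", "adjective"),
    "ramas": ("rama", "noun"),
    "madera": ("madera", "noun"),
    "dientes": ("diente", "noun"),
    "peligroso": ("peligroso", "adjective"),
}


class DictionaryTagger:
    """Lookup tagger over an explicit surface -> (lemma, pos) mapping.

    Unknown words fall back to ``oov`` ("skip" drops them, "noun" keeps
    them as their own lemma tagged noun — useful for synthetic data whose
    vocabulary is closed).
    """

    def __init__(
        self,
        lexicon: Mapping[str, tuple[str, str]],
        function_words: frozenset[str] = frozenset(),
        oov: str = "skip",
    ) -> None:
        if oov not in ("skip", "noun"):
            raise ValueError("oov must be 'skip' or 'noun'")
        self.lexicon = {casefold_lemma(k): v for k, v in lexicon.items()}
        self.function_words = function_words
        self.oov = oov

    def __call__(self, word: str) -> Optional[tuple[str, str]]:
        key = casefold_lemma(word)
        if key in self.function_words:
            return None
        hit = self.lexicon.get(key)
        if hit is not None:
            return hit
        if self.oov == "noun":
            return (key, "noun")
        return None


def spanish_demo_tagger() -> DictionaryTagger:
    """Tagger over the built-in Spanish demo dictionary (tests and examples)."""
    return DictionaryTagger(SPANISH_DEMO_LEXICON, SPANISH_FUNCTION_WORDS, oov="skip")
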