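"""Packaged default English stopword list.

The choice of stopword list measurably shifts string-metric scores (153- vs
174-word lists give different Jaccard/q-gram correlations on the same
benchmark), so the list is treated as data: callers may pass their own via
``PreprocessConfig(stopword_list=...)`` or load one from a file with
:func:`load_stopwords`.  The packaged default is a standard ~150-word English
list of determiners, pronouns, auxiliaries, conjunctions and particles.
"""

from __future__ import annotations

from pathlib import Path

_DEFAULT = """
i me my myself we our ours ourselves you your yours yourself yourselves
he him his himself she her hers herself it its itself they them their
theirs themselves what which who whom this that these those am is are
was were be been being have has had having do does did doing a an the
and but if or because as until while of at by for with about against
between into through during before after above below to from up down in
out on off over under again further then once here there when where why
how all any both each few more most other some such no nor not only own
same so than too very s t can will just don should now d ll m o re ve y
ain aren couldn didn doesn hadn hasn haven isn ma mightn mustn needn
shan shouldn wasn weren won wouldn
"""

DEFAULT_STOPWORDS: frozenset[str] = frozenset(_DEFAULT.split())

#: The eight punctuation marks removed alongside stopwords: full stop, comma,
#: colon, semicolon, question mark, exclamation mark, slash, dash.
DEFAULT_PUNCTUATION: frozenset[str] = frozenset({".", ",", ":", ";", "?", "!", "/", "-"})


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a whitespace/newline-separated stopword file (case-folded)."""
    text = Path(path).read_text(encoding="utf-8")
    return frozenset(tok.lower() for tok in text.split())
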