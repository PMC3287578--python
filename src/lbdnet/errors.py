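"""Exception hierarchy for lbdnet.

Input problems (bad lexicon or corpus files, unknown entities) raise
subclasses of :class:`InputError`; internal consistency violations raise
subclasses of :class:`ConsistencyError`. The CLI maps the former to exit
code 1 and the latter to exit code 2.
"""


class LbdnetError(Exception):
    """Base class for all lbdnet errors."""


class InputError(LbdnetError):
    """A problem with user-supplied input (files, names, options)."""


class ConsistencyError(LbdnetError):
    """An internal invariant does not hold (corrupt index or network)."""


# --- lexicon loading ---------------------------------------------------

class LexiconError(InputError):
    """Base class for lexicon validation failures."""


class LexiconFormatError(LexiconError):
    """The lexicon file cannot be parsed in the expected JSON shape."""


class DuplicateRepresentativeError(LexiconError):
    """Two clusters share the same representative name."""


class SharedSynonymError(LexiconError):
    """A synonym appears in more than one cluster."""


class MissingCategoryError(LexiconError):
    """A cluster has an empty or missing category."""


# --- corpus loading ----------------------------------------------------

class CorpusError(InputError):
    """Base class for corpus validation failures."""


class CorpusFormatError(CorpusError):
    """A corpus record cannot be parsed in the expected JSON-lines shape."""


class DuplicateDocumentError(CorpusError):
    """Two documents carry the same id."""


class InvalidDateError(CorpusError):
    """A document's issue date is not a valid ISO-8601 calendar date."""


class EmptyDocumentError(CorpusError):
    """A document has an empty text body."""


# --- retrieval / network -----------------------------------------------

class UnknownEntityError(InputError):
    """A query names an entity that is not in the lexicon."""


class UndefinedEntityError(LbdnetError):
    """idf requested for an entity occurring in zero documents."""


class InconsistentIndexError(ConsistencyError):
    """Occurrence counts violate their own invariants (f > max_f, n > N)."""


class HistoryError(InputError):
    """An inference history was requested for a cell that is not new."""
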