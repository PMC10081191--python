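"""Exception vocabulary shared across the package.

The CLI maps these onto fixed exit codes (parse/build -> 2, empty
input mapping -> 3, identifier lookup -> 4) so shell pipelines can
branch on failure class.
"""


class MetaboGoError(Exception):
    """Base class for all package errors."""


class FormatError(MetaboGoError):
    """A source file violates its declared dialect (bad stanza, wrong
    column count, ...). Messages carry a line number or byte offset."""


class BuildError(MetaboGoError):
    """Knowledgebase assembly produced an unusable result, e.g. an
    empty GO-linked compound universe."""


class AnalysisError(MetaboGoError):
    """An over-representation run cannot proceed, e.g. no input
    compound mapped into the knowledgebase."""


class KBLookupError(MetaboGoError):
    """An identifier (GO term, compound, gene, ...) is absent from the
    knowledgebase."""
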