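"""Exception hierarchy for the pipeline.

All errors derive from :class:`TurboproxError` so callers can catch the
package's failures with one clause; configuration/validation problems are
kept distinct from malformed input files so the CLI can map them to
different exit codes.
"""


class TurboproxError(Exception):
    """Base class for all errors raised by turboprox."""


class FormatError(TurboproxError):
    """A file's structure is wrong (missing column, bad header)."""


class ParseError(TurboproxError):
    """A data row could not be parsed; the message cites the row."""


class ValidationError(TurboproxError):
    """Inputs are structurally fine but violate an invariant."""


class ConfigError(TurboproxError):
    """Pipeline configuration is invalid or references missing files."""
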