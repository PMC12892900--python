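"""Exception hierarchy.

All germkit errors derive from :class:`GermkitError` so callers can catch
package failures without masking programming errors.
"""


class GermkitError(Exception):
    """Base class for all germkit errors."""


class FormatError(GermkitError):
    """A file or table violates its declared format contract."""


class ValidationError(GermkitError):
    """An in-memory object or configuration violates its invariants."""
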