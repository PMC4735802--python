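"""Exception hierarchy shared across the package."""


class ChannelPoreError(Exception):
    """Base class for all package errors."""


class ParseError(ChannelPoreError):
    """A structure file could not be read or parsed."""


class EmptySelectionError(ChannelPoreError):
    """Filtering left no atoms."""


class RadiusLookupError(ChannelPoreError):
    """An element has no van der Waals radius in the requested set."""


class AlignmentError(ChannelPoreError):
    """Pore-axis alignment could not be performed as requested."""


class GridError(ChannelPoreError):
    """Invalid grid specification or degenerate clearance field."""


class RegionError(ChannelPoreError):
    """A seed/target region is invalid on the given grid."""


class FixtureSpecError(ChannelPoreError):
    """A synthetic-fixture specification violates its invariants."""


class UnitsError(ChannelPoreError):
    """A physical parameter is outside its valid domain."""
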