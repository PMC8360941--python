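"""Exception hierarchy for biplink.

All validation failures raise a subclass of :class:`BiplinkError`, so callers
(and the CLI) can distinguish data problems (exit 1) from usage problems.
"""


class BiplinkError(Exception):
    """Base class for all biplink errors."""


class BipartitenessError(BiplinkError):
    """A node appears on both sides, or a link joins two same-side nodes."""


class ParseError(BiplinkError):
    """Malformed input row; the message names the offending line."""


class FormatError(BiplinkError):
    """Adjacency-matrix cell outside {0,1} or otherwise malformed file."""


class LabelError(BiplinkError):
    """Duplicate row or column label in a labeled adjacency matrix."""


class NodeLookupError(BiplinkError):
    """Queried node is not part of the network."""


class SideError(BiplinkError):
    """A node was supplied on the wrong side of the bipartition."""


class VocabularyError(BiplinkError):
    """Unknown index name or mode outside the closed vocabulary."""


class TemporalError(BiplinkError):
    """Missing or unparseable timestamp on a temporal operation."""


class CoverageError(BiplinkError):
    """Conditional-probability matrix does not cover a required disease."""


class ParameterError(BiplinkError):
    """Out-of-range parameter (probe fraction, k, thresholds...)."""


class EvaluationError(BiplinkError):
    """Degenerate evaluation input (empty probe set, single-class labels)."""


class ContractError(BiplinkError):
    """Caller violated an operation contract (e.g. existing link passed as candidate)."""


class SpecError(BiplinkError):
    """Infeasible simulation specification."""
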