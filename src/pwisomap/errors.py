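"""Exception hierarchy for pwisomap."""


class PwisomapError(Exception):
    """Base class for all pwisomap errors."""


class ValidationError(PwisomapError, ValueError):
    """An input violates a documented invariant."""


class ParseError(PwisomapError, ValueError):
    """A file could not be parsed; message names the offending location."""


class SingularCovarianceError(PwisomapError, ValueError):
    """Covariance matrix is singular and no regularization was requested."""


class DisconnectedGraphError(PwisomapError, ValueError):
    """Neighbourhood graph has more than one connected component.

    Carries the component sizes so callers can decide whether to fall back
    to the largest component.
    """

    def __init__(self, component_sizes):
        self.component_sizes = sorted(component_sizes, reverse=True)
        super().__init__(
            "neighbourhood graph is disconnected (component sizes: "
            f"{self.component_sizes}); increase k_neighbors or enable the "
            "largest-component fallback"
        )
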