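"""Exception hierarchy for osmopump.

Everything raised deliberately by the package derives from
:class:`OsmopumpError`, so callers can catch one base class. Subclasses
additionally derive from the closest builtin (ValueError / RuntimeError)
so idiomatic ``except ValueError`` code keeps working.
"""


class OsmopumpError(Exception):
    """Base class for all osmopump errors."""


class ParameterError(OsmopumpError, ValueError):
    """A user-supplied parameter is out of its valid range."""


class InputError(OsmopumpError, ValueError):
    """Input data (coordinates, ids, fields) violate a precondition."""


class FormatError(OsmopumpError, ValueError):
    """A file does not conform to the expected dialect."""


class ConfigurationError(OsmopumpError, ValueError):
    """System/groups/config are inconsistent (e.g. missing index group)."""


class ConsistencyError(OsmopumpError, ValueError):
    """Cross-file bookkeeping mismatch (e.g. TOP counts vs GRO molecules)."""


class StateError(OsmopumpError, RuntimeError):
    """An operation was called in a state where it is undefined."""


class GeometryError(OsmopumpError, ValueError):
    """Degenerate or infeasible geometry."""


class ReconstructionError(OsmopumpError, RuntimeError):
    """PBC unwrapping or surface reconstruction failed."""


class AmbiguousOuterError(OsmopumpError, RuntimeError):
    """The corner-bin vote for the outer compartment is tied or empty.

    This happens when the enclosed object crosses a box corner under
    periodic boundaries; recentre the system on the vesicle and retry.
    """


class MultiCompartmentError(OsmopumpError, RuntimeError):
    """More than two solvent compartments: pumping refuses to run."""


class SolventExhaustedError(OsmopumpError, RuntimeError):
    """No solvent molecules are available for pumping; run terminates."""


class EngineFailure(OsmopumpError, RuntimeError):
    """The simulation engine reported a failed run for this cycle."""
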