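"""Exception hierarchy shared across the package."""


class VQEBenchError(Exception):
    """Base class for all package-specific errors."""


class UnknownElementError(VQEBenchError):
    """An element symbol is missing from the basis-counting rules."""


class ActiveSpaceError(VQEBenchError):
    """Active-space bookkeeping is inconsistent (accounting, range or overlap)."""


class FCIDUMPError(VQEBenchError):
    """An FCIDUMP stream is malformed (header or record level)."""


class HermiticityError(VQEBenchError):
    """An operator expected to be Hermitian is not."""


class CapacityError(VQEBenchError):
    """A requested computation exceeds a configured size cap."""


class ArityError(VQEBenchError):
    """Parameter vector, state or Hamiltonian sizes are inconsistent."""


class GateError(VQEBenchError):
    """A gate is malformed or unsupported for the requested operation."""


class OptimizationError(VQEBenchError):
    """The optimizer diverged; carries the trajectory recorded so far."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory


class ConfigError(VQEBenchError):
    """A benchmark configuration is invalid."""


class InputError(VQEBenchError):
    """An external input (file, fixture name) could not be resolved."""
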