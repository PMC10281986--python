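"""Exception types raised across the toolkit."""


class NucdeformError(Exception):
    """Base class for all package errors."""


class StructureParseError(NucdeformError):
    """A coordinate file could not be parsed under the requested dialect."""


class FormatError(NucdeformError):
    """Unknown or unsupported file format."""


class RoleError(NucdeformError):
    """Chain-role assignment conflict, missing role, or ambiguity."""


class AnchorError(NucdeformError):
    """A dyad specification could not be resolved on a strand."""


class CorrespondenceError(NucdeformError):
    """No residue pairs could be matched between two models."""


class InsufficientPointsError(NucdeformError):
    """Fewer than three point pairs for a superposition."""


class PruningCollapseError(NucdeformError):
    """Iterative pruning left fewer than three anchor pairs."""


class WindowError(NucdeformError):
    """An RMSD window contains no positions modeled in both structures."""


class GrooveUndefinedError(NucdeformError):
    """Minor-groove width cannot be measured (missing phosphates)."""


class TrackError(NucdeformError):
    """A register track is empty or its strand is absent."""


class ScoreUndefinedError(NucdeformError):
    """Flipped-nucleotide score needs neighbors that are not modeled."""


class GroupingError(NucdeformError):
    """Atom groups for an interface computation are empty or overlap."""


class ParameterError(NucdeformError):
    """Invalid geometry or perturbation parameters."""


class StageError(NucdeformError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
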