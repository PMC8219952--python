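"""Exception hierarchy shared across the pipeline."""


class TcrDockEvalError(Exception):
    """Base class for all pipeline errors."""


class EmptyStructureError(TcrDockEvalError):
    """A coordinate file contained no ATOM records."""


class MissingChainError(TcrDockEvalError):
    """A role points at a chain that is not present in the structure."""


class MappingError(TcrDockEvalError):
    """A role map is inconsistent (duplicate sources, uncovered chains)."""


class MissingRoleError(TcrDockEvalError):
    """A requested role is absent from a structure's role map."""


class ChainIdentityError(TcrDockEvalError):
    """A chain pair aligned below the required sequence identity."""

    def __init__(self, role: str, identity: float, min_identity: float):
        self.role = role
        self.identity = identity
        self.min_identity = min_identity
        super().__init__(
            f"chain pair for role {role!r} has identity {identity:.3f} "
            f"< required {min_identity:.3f}"
        )


class CorrespondenceError(TcrDockEvalError):
    """Two coordinate sets do not carry matching atom labels."""


class DegenerateInputError(TcrDockEvalError):
    """Too few points for a rigid superposition."""


class MissingReferenceError(TcrDockEvalError):
    """An operation needs the bound reference structure and none was given."""


class MissingStructureError(TcrDockEvalError):
    """A docking case lacks a required unbound structure."""


class InvalidReferenceError(TcrDockEvalError):
    """The reference complex has no receptor-ligand contacts."""


class MissingLoopError(TcrDockEvalError):
    """A requested CDR loop has no residues on one side of a comparison."""


class GenerationError(TcrDockEvalError):
    """The synthetic generator failed to realise a requested property."""
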