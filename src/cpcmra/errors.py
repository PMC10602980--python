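"""Exception types shared across the package."""


class CPCMRAError(Exception):
    """Base class for all package errors."""


class ValidationError(CPCMRAError, ValueError):
    """An input violated a documented precondition or invariant."""


class IncompleteDatasetError(CPCMRAError):
    """A 4D flow dataset is missing one of its required channels."""

    def __init__(self, channel: str):
        self.channel = channel
        super().__init__(f"incomplete dataset: missing channel '{channel}'")


class GridMismatchError(CPCMRAError):
    """Volumes that must share a voxel grid do not."""


class StackMismatchError(CPCMRAError):
    """Image stacks that must share geometry do not."""
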