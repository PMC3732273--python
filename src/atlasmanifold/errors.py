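"""Exception types shared across the package."""

from __future__ import annotations


class AtlasManifoldError(Exception):
    """Base class for all package-specific errors."""


class GridMismatchError(AtlasManifoldError, ValueError):
    """Two volumes do not share the same voxel grid."""


class DisconnectedGraphError(AtlasManifoldError, RuntimeError):
    """The k-nearest-neighbour graph is not connected.

    Signals that ``k_D`` is too small for the library at hand.  Carries the
    per-node component labels so callers can report or skip.
    """

    def __init__(self, labels, n_components: int):
        self.labels = labels
        self.n_components = int(n_components)
        super().__init__(
            f"neighbour graph has {self.n_components} connected components; "
            "increase k_D or inspect the library"
        )


class ExtensionError(AtlasManifoldError, RuntimeError):
    """Out-of-sample extension cannot place the target on the manifold."""


class SingularLocalSystemError(AtlasManifoldError, RuntimeError):
    """A local LLE weight system is singular even after regularization."""


class FoldingWarpError(AtlasManifoldError, ValueError):
    """A synthetic displacement field self-folds (non-positive Jacobian)."""
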