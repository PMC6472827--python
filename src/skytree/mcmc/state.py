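"""Joint MCMC state over (tree, site model, clock, scalar parameters)."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

from ..likelihood import ClockModel
from ..substitution import SiteModel
from ..trees import TimeTree

__all__ = ["McmcState", "Target"]

# A target density maps a state to an (unnormalized) log posterior.
Target = Callable[["McmcState"], float]


@dataclass(frozen=True)
class McmcState:
    """Immutable snapshot of the sampler state.

    ``params`` holds named scalars (tree-prior parameters, clock rate
    hyperparameters, ...).  Components not under inference stay ``None``.
    """

    tree: Optional[TimeTree] = None
    site: Optional[SiteModel] = None
    clock: Optional[ClockModel] = None
    params: dict[str, float] = field(default_factory=dict)

    def with_(self, **kw) -> "McmcState":
        return replace(self, **kw)

    def with_param(self, key: str, value: float) -> "McmcState":
        new = dict(self.params)
        new[key] = value
        return replace(self, params=new)
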