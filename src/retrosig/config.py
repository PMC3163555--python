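"""Run configuration shared across the design pipeline.

Every tunable of the stack lives here so that command-line outputs can embed
the full resolved configuration for provenance and byte-identical replay.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import List, Tuple

#: compounds excluded from backward expansion: ubiquitous cofactors whose
#: regeneration is the chassis' own business, not the pathway designer's
DEFAULT_CURRENCY: Tuple[str, ...] = (
    "WATER",
    "ATP",
    "ADP",
    "NAD",
    "NADH",
    "NADP",
    "NADPH",
    "COA",
    "PI",
    "PPI",
    "O2",
    "CO2",
    "NH3",
)


@dataclass
class RunConfig:
    """Resolved parameters for a design run.

    Heights are heavy-atom signature heights; weights follow the pathway
    cost W = lambda_path * sum(enzyme costs) + lambda_tox * sum(tox) +
    lambda_flux / (1 + v_c).
    """

    height: int = 3                    # working signature height
    kmer: int = 3                      # amino-acid k-mer for string kernels
    omega_p: float = 1.0               # promiscuity weight in enzyme cost
    omega_e: float = 1.0               # performance weight in enzyme cost
    lambda_path: float = 1.0           # fixed normalisation anchor
    lambda_tox: float = 0.0
    lambda_flux: float = 0.0
    max_substitutions: int = 1000      # per-reaction cap during expansion
    max_class_size: int = 50           # signature-class cap during expansion
    max_depth: int = 10                # retrosynthesis depth bound (reactions)
    max_pathways: int = 10_000
    currency: List[str] = field(default_factory=lambda: list(DEFAULT_CURRENCY))
    gibbs_threshold: float = 0.0       # kJ/mol feasibility cut ...
    gibbs_tolerance: float = 5.0       # ... with this much slack
    group_height: int = 1              # group-contribution subgroup height
    seed: int = 0
    tanimoto_convention: str = "minmax"        # or "dot"
    similarity_representation: str = "explicit_h"  # calibrated; or "heavy"
    phi_grid_points: int = 21          # growth-fraction grid for nominal flux

    def validate(self) -> "RunConfig":
        if self.height < 0 or self.kmer < 1:
            raise ValueError("height must be >= 0 and kmer >= 1")
        for name in ("omega_p", "omega_e", "lambda_path", "lambda_tox", "lambda_flux"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tanimoto_convention not in ("minmax", "dot"):
            raise ValueError("tanimoto_convention must be 'minmax' or 'dot'")
        if self.similarity_representation not in ("explicit_h", "heavy"):
            raise ValueError("similarity_representation must be 'explicit_h' or 'heavy'")
        if self.max_depth < 1 or self.phi_grid_points < 1:
            raise ValueError("max_depth and phi_grid_points must be >= 1")
        return self

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text)).validate()

    def header_lines(self) -> List[str]:
        """Provenance header embedded in every TSV the tools write."""
        return [f"# retrosig-config {self.to_json()}"]
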