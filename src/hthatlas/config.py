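"""Pipeline configuration.

All distance cutoffs and algorithm parameters used across the pipeline live in
one flat dataclass so that a single structured-text (YAML) file can override
them.  The defaults are the published values of the HTH curation/alignment
procedure: recognition-helix candidacy at a 5 A mean over the closest five
contiguous residues, a 6.5 A per-residue orientation cutoff, an 18 A
tri-helical bundle cutoff, a 2 A DNA-RMSD gate (delta) for candidate
alignments and a minimum recognition-helix overlap of 8 residues.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class Config:
    # --- HTH detection ---
    candidacy_cutoff: float = 5.0      # A, strict: mean of window < cutoff
    candidacy_window: int = 5          # residues in the contiguous window
    orientation_cutoff: float = 6.5    # A, inclusive, per window residue
    trihelix_cutoff: float = 18.0      # A, Ca-Ca from central residue
    min_helices: int = 3               # tri-helical bundle requirement
    # geometric alpha-helix assignment (Ca(i)-Ca(i+3), Ca(i)-Ca(i+4) windows)
    helix_d13: tuple[float, float] = (4.5, 6.5)
    helix_d14: tuple[float, float] = (5.5, 7.5)

    # --- duplex standardization ---
    pair_c1_distance: float = 10.5     # A, C1'-C1' across a basepair
    pair_c1_tolerance: float = 1.5     # A

    # --- redundancy elimination ---
    recseq_flank: int = 20             # residues each side -> 41-symbol window
    max_shift: int = 15                # |shift| bound from the 11-residue rule

    # --- structural alignment ---
    delta: float = 2.0                 # A, DNA RMSD gate (strict <)
    min_overlap: int = 8               # m, recognition-helix overlap
    region_span: int = 5               # bp per canonical matching region

    # --- atlas / clustering ---
    ap_damping: float = 0.9
    ap_max_iter: int = 1000
    ap_convergence_iter: int = 50
    cluster_distance_bound: float = 3.5  # A, max member-to-exemplar RMSD
    unalignable_distance: float = 1.0e4  # sentinel distance for gated-out pairs

    # --- contacts / PWM ---
    contact_cutoff: float = 5.0        # A
    pseudocount: float = 1.0           # Laplace smoothing alpha

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("helix_d13", "helix_d14"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["helix_d13"] = list(data["helix_d13"])
        data["helix_d14"] = list(data["helix_d14"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


DEFAULT_CONFIG = Config()
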