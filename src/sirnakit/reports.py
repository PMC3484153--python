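"""Versioned TSV report output.

Every report carries a commented header with the tool version, a config
hash and the seed, so that identical configs reproduce byte-identical
files.  Guide and sense strands are written as RNA (5'->3'); coordinates
are 1-based inclusive, with mismatch positions numbered on the guide
5'->3'.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .design import SiRNACandidate
from .offtarget import MismatchHit
from .qpcr import ExtinctionEstimate
from .transcripts import to_rna


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: str | Path, config: dict | None = None) -> None:
    """Write a DataFrame as TSV under a commented provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# sirnakit {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {config_hash(config)}\n")
            for key in sorted(config):
                fh.write(f"# {key}={config[key]}\n")
        df.to_csv(fh, sep="\t", index=False)


def candidates_frame(candidates: list[SiRNACandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target_id": [c.target_id for c in candidates],
            "start": [c.start for c in candidates],
            "sense": [to_rna(c.sense) for c in candidates],
            "guide": [to_rna(c.guide) for c in candidates],
            "location": [str(c.location) for c in candidates],
            "base_score": [c.base_score for c in candidates],
            "corrected_score": [c.corrected_score for c in candidates],
            "n_offtargets": [c.n_offtargets for c in candidates],
            "flags": [",".join(sorted(c.flags)) for c in candidates],
        }
    )


def hits_frame(hits: list[MismatchHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pattern_id": [h.pattern_id for h in hits],
            "subject_id": [h.subject_id for h in hits],
            "subject_start": [h.subject_start for h in hits],
            "mismatch_count": [h.mismatch_count for h in hits],
            "mismatch_positions": [
                ",".join(map(str, h.mismatch_positions)) for h in hits
            ],
        }
    )


def extinction_frame(estimates: list[ExtinctionEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sirna_id": [e.sirna_id for e in estimates],
            "q": [e.q for e in estimates],
            "knockdown_pct": [e.knockdown_pct for e in estimates],
            "log2_sd": [e.log2_sd for e in estimates],
            "n_reps": [e.n_reps for e in estimates],
            "normalizers": [",".join(e.normalizers) for e in estimates],
        }
    )
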