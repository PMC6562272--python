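"""File-format contracts and run configuration.

Two tabular text outputs define the on-disk session format:

``session_log.csv``
    One row per 1-second bin with columns ``subject_id``, ``group``,
    ``block_index`` (1-based), ``block_role``, ``p_contingent``,
    ``p_noncontingent``, ``bin_index`` (0-based), ``pressed``,
    ``rewarded``.  Booleans are written as 0/1; the dialect is
    comma-separated UTF-8 with a header row and "." decimals.

``ratings.csv``
    One row per block: ``subject_id``, ``block_index``, ``rating``.

Both are lossless: a session list round-trips through the pair of files
bit-for-bit, which is what makes simulation runs reproducible artefacts
rather than transient state.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .agents import GROUP_PRESETS, GROUP_SIZES, AgentProfile
from .schedule import BinRecord, BlockResult, BlockSpec, SessionRecord

__all__ = [
    "SESSION_LOG_COLUMNS",
    "session_log_frame",
    "ratings_frame",
    "write_session_files",
    "read_session_files",
    "sessions_from_frames",
    "GroupConfig",
    "RunConfig",
    "default_config",
    "load_config",
    "build_manifest",
    "load_deposited_measures",
]

SESSION_LOG_COLUMNS = [
    "subject_id",
    "group",
    "block_index",
    "block_role",
    "p_contingent",
    "p_noncontingent",
    "bin_index",
    "pressed",
    "rewarded",
]

RATINGS_COLUMNS = ["subject_id", "block_index", "rating"]


def session_log_frame(sessions: Iterable[SessionRecord]) -> pd.DataFrame:
    """Per-bin long-format log of a session list."""
    rows = []
    for s in sessions:
        for bi, block in enumerate(s.blocks, start=1):
            for i, rec in enumerate(block.bins):
                rows.append(
                    (
                        s.subject_id,
                        s.group,
                        bi,
                        block.spec.role,
                        block.spec.p_contingent,
                        block.spec.p_noncontingent,
                        i,
                        int(rec.pressed),
                        int(rec.rewarded),
                    )
                )
    return pd.DataFrame(rows, columns=SESSION_LOG_COLUMNS)


def ratings_frame(sessions: Iterable[SessionRecord]) -> pd.DataFrame:
    """Per-block causal-rating table of a session list."""
    rows = []
    for s in sessions:
        for bi, block in enumerate(s.blocks, start=1):
            rows.append((s.subject_id, bi, block.rating))
    return pd.DataFrame(rows, columns=RATINGS_COLUMNS)


def write_session_files(
    sessions: Iterable[SessionRecord], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write ``session_log.csv`` and ``ratings.csv`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions = list(sessions)
    log_path = out_dir / "session_log.csv"
    ratings_path = out_dir / "ratings.csv"
    session_log_frame(sessions).to_csv(log_path, index=False)
    ratings_frame(sessions).to_csv(ratings_path, index=False)
    return log_path, ratings_path


def sessions_from_frames(
    log: pd.DataFrame, ratings: Optional[pd.DataFrame] = None
) -> list[SessionRecord]:
    """Rebuild SessionRecords from the log (and optional ratings) tables."""
    missing = [c for c in SESSION_LOG_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"session log is missing columns: {missing}")
    rating_of: dict[tuple[str, int], float] = {}
    if ratings is not None:
        bad = [c for c in RATINGS_COLUMNS if c not in ratings.columns]
        if bad:
            raise ValueError(f"ratings table is missing columns: {bad}")
        for row in ratings.itertuples(index=False):
            if not pd.isna(row.rating):
                rating_of[(str(row.subject_id), int(row.block_index))] = float(
                    row.rating
                )
    sessions: list[SessionRecord] = []
    for subject_id, sub in log.groupby("subject_id", sort=False):
        record = SessionRecord(
            subject_id=str(subject_id), group=str(sub["group"].iloc[0])
        )
        for block_index, blk in sub.groupby("block_index", sort=True):
            blk = blk.sort_values("bin_index")
            spec = BlockSpec(
                p_contingent=float(blk["p_contingent"].iloc[0]),
                p_noncontingent=float(blk["p_noncontingent"].iloc[0]),
                duration_bins=len(blk),
                role=str(blk["block_role"].iloc[0]),
            )
            bins = [
                BinRecord(pressed=bool(p), rewarded=bool(r))
                for p, r in zip(blk["pressed"], blk["rewarded"])
            ]
            record.blocks.append(
                BlockResult(
                    spec=spec,
                    bins=bins,
                    rating=rating_of.get((str(subject_id), int(block_index))),
                )
            )
        sessions.append(record)
    return sessions


def read_session_files(run_dir: str | Path) -> list[SessionRecord]:
    """Read the session files written by :func:`write_session_files`."""
    run_dir = Path(run_dir)
    log = pd.read_csv(run_dir / "session_log.csv")
    ratings_path = run_dir / "ratings.csv"
    ratings = pd.read_csv(ratings_path) if ratings_path.exists() else None
    return sessions_from_frames(log, ratings)


class GroupConfig(BaseModel):
    """One cohort's profile parameters and size.

    ``preset`` names one of the built-in group profiles; any explicit
    field overrides the preset value.  Unknown keys are rejected.
    """

    model_config = ConfigDict(extra="forbid")

    preset: Optional[str] = None
    n_subjects: Optional[int] = Field(default=None, ge=1)
    learning_rate: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    policy_intercept: Optional[float] = None
    policy_slope: Optional[float] = Field(default=None, ge=0.0)
    rating_gain: Optional[float] = Field(default=None, gt=0.0)
    weight_contingent: Optional[float] = Field(default=None, ge=0.0)
    weight_noncontingent: Optional[float] = Field(default=None, ge=0.0)
    weight_reward_rate: Optional[float] = Field(default=None, ge=0.0)
    rating_bias: Optional[float] = None
    rating_noise_sd: Optional[float] = Field(default=None, ge=0.0)
    round_ratings: Optional[bool] = None

    def resolve(self, group_name: str) -> tuple[AgentProfile, int]:
        preset_name = self.preset if self.preset is not None else group_name
        if preset_name in GROUP_PRESETS:
            base = GROUP_PRESETS[preset_name]
            default_n = GROUP_SIZES.get(preset_name)
        elif self.preset is None:
            base = AgentProfile()
            default_n = None
        else:
            raise ValueError(
                f"unknown preset {preset_name!r}; "
                f"available: {sorted(GROUP_PRESETS)}"
            )
        overrides = {
            k: v
            for k, v in self.model_dump().items()
            if k not in ("preset", "n_subjects") and v is not None
        }
        profile = AgentProfile(**{**base.__dict__, **overrides})
        n = self.n_subjects if self.n_subjects is not None else default_n
        if n is None:
            raise ValueError(f"group {group_name!r} needs n_subjects")
        return profile, n


class RunConfig(BaseModel):
    """Configuration of a simulation run.

    The master seed is mandatory; it is the single source of randomness
    for the whole run (one sub-seed per group, then per subject).
    Unknown keys anywhere in the config are rejected.
    """

    model_config = ConfigDict(extra="forbid")

    seed: Optional[int] = Field(default=None, ge=0)
    duration_bins: int = Field(default=60, ge=1)
    groups: dict[str, GroupConfig] = Field(default_factory=dict)

    def resolved_groups(self) -> dict[str, tuple[AgentProfile, int]]:
        groups = self.groups or {
            name: GroupConfig() for name in GROUP_PRESETS
        }
        return {name: cfg.resolve(name) for name, cfg in groups.items()}


def default_config(seed: Optional[int] = None) -> RunConfig:
    """Five-group study configuration with the built-in presets."""
    return RunConfig(
        seed=seed,
        groups={name: GroupConfig() for name in GROUP_PRESETS},
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def build_manifest(
    config: RunConfig, seed: int, n_sessions: int
) -> dict:
    """Reproducibility manifest for a simulation run."""
    cfg_json = config.model_dump_json()
    import numpy
    import scipy

    return {
        "freeop_version": __version__,
        "seed": int(seed),
        "n_sessions": int(n_sessions),
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
    }


#: Default column mapping for the study's deposited task data
#: (doi:10.17863/CAM.17553).  Keys are our measures-table columns,
#: values the column names in the deposited per-block file; adjust via
#: the ``mapping`` argument if the deposited layout differs.
DEPOSITED_MAPPING = {
    "subject_id": "subject",
    "group": "group",
    "delta_p": "contingency",
    "response_rate": "response_rate",
    "rating": "rating",
}


def load_deposited_measures(
    path: str | Path, mapping: Optional[dict[str, str]] = None
) -> pd.DataFrame:
    """Load the deposited per-block task data as a measures table.

    The study's raw data are archived at doi:10.17863/CAM.17553 and are
    not bundled here; download the per-block file and point this loader
    at it.  ``mapping`` renames deposited columns onto the measures
    schema (``subject_id``, ``group``, ``delta_p``, ``response_rate``,
    ``rating``); the resulting frame feeds :func:`freeop.stats.mixed_anova`
    directly, e.g. to reproduce the printed F statistics.
    """
    mapping = DEPOSITED_MAPPING if mapping is None else mapping
    df = pd.read_csv(path)
    missing = [src for src in mapping.values() if src not in df.columns]
    if missing:
        raise ValueError(
            f"deposited file lacks expected columns {missing}; "
            "pass a column mapping"
        )
    out = df.rename(columns={src: dst for dst, src in mapping.items()})
    return out[list(mapping.keys())]
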