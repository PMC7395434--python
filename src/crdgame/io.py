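"""CSV/JSON schemas, validation, manifests and seed plumbing.

All tables are UTF-8 comma-separated files with a mandatory header, '.'
decimals and LF newlines.  The gameplay schema is long format, one row per
player-round; validation enforces the {0,2,4} menu, the 1..10 round range
and exact capital accounting.  A run manifest records the design, the seed
fan-out and SHA-256 digests of every output so any stage can be reproduced
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import GameConfig

__all__ = [
    "GAMEPLAY_COLUMNS",
    "QUESTIONNAIRE_COLUMNS",
    "read_gameplay",
    "write_gameplay",
    "read_questionnaire",
    "write_questionnaire",
    "config_to_json",
    "config_from_json",
    "stage_seeds",
    "write_manifest",
]

GAMEPLAY_COLUMNS = [
    "session_id", "arm", "group_id", "group_size", "round",
    "player_id", "investment", "capital_after",
]
QUESTIONNAIRE_COLUMNS = [
    "session_id", "arm", "group_id", "round", "player_id", "question", "answer",
]

_CSV_KW = dict(index=False, lineterminator="\n")


def validate_gameplay(df: pd.DataFrame, n_rounds: int = 10, endowment: int = 40) -> pd.DataFrame:
    """Schema and accounting checks; returns the frame untouched on success."""
    missing = [c for c in GAMEPLAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gameplay CSV missing columns: {missing}")
    bad_arm = set(df["arm"]) - {"control", "treatment"}
    if bad_arm:
        raise ValueError(f"unknown arm values: {sorted(bad_arm)}")
    bad_inv = df[~df["investment"].isin([0, 2, 4])]
    if len(bad_inv):
        r = bad_inv.iloc[0]
        raise ValueError(
            f"investment {r['investment']} outside menu {{0,2,4}} "
            f"(player {r['player_id']}, round {r['round']})"
        )
    bad_round = df[(df["round"] < 1) | (df["round"] > n_rounds)]
    if len(bad_round):
        r = bad_round.iloc[0]
        raise ValueError(f"round {r['round']} outside 1..{n_rounds} (player {r['player_id']})")
    for pid, g in df.groupby("player_id", sort=False):
        g = g.sort_values("round")
        expected = endowment - g["investment"].cumsum()
        if not (g["capital_after"].to_numpy() == expected.to_numpy()).all():
            bad = g[g["capital_after"].to_numpy() != expected.to_numpy()].iloc[0]
            raise ValueError(
                f"capital accounting violated for player {pid} at round {bad['round']}: "
                f"capital_after {bad['capital_after']} != {endowment} - cumulative investment"
            )
    return df


def read_gameplay(path: str | Path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_gameplay(df) if validate else df


def write_gameplay(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_gameplay(df)
    df.to_csv(path, **_CSV_KW)
    return path


def read_questionnaire(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in QUESTIONNAIRE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"questionnaire CSV missing columns: {missing}")
    if len(df) and not df["answer"].isin([0, 1]).all():
        raise ValueError("answers must be 0/1")
    return df


def write_questionnaire(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, **_CSV_KW)
    return path


def config_to_json(config: GameConfig, path: str | Path | None = None) -> str:
    doc = asdict(config)
    doc["target"] = config.target
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def config_from_json(source: str | Path) -> GameConfig:
    text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
    doc = json.loads(text)
    doc.pop("target", None)  # derived, never stored
    doc["choices"] = tuple(doc.get("choices", (0, 2, 4)))
    return GameConfig(**doc)


def stage_seeds(master_seed: int, stages: tuple[str, ...]) -> dict[str, int]:
    """Deterministic fan-out of one master seed into per-stage seeds.

    Uses numpy's SeedSequence spawning so stages are statistically
    independent yet individually reproducible; seeds stay below 2**31.
    """
    children = np.random.SeedSequence(master_seed).spawn(len(stages))
    return {
        stage: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for stage, child in zip(stages, children)
    }


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    out_dir: str | Path, seeds: dict[str, int], config: dict, files: list[str | Path]
) -> Path:
    """Record seeds, configuration and output digests for reproducibility."""
    out_dir = Path(out_dir)
    manifest = {
        "package": "crdgame",
        "seeds": seeds,
        "config": config,
        "outputs": {str(Path(f).name): _digest(Path(f)) for f in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path
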