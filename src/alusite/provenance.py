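"""Run manifests embedded in every machine-readable report.

Reports carry the command, the resolved configuration digest, a SHA-256
digest per input file, the seed and the tool version, so a result can be
traced to exactly the inputs that produced it. Wall-clock timestamps are
logged to the console stream only, keeping reports byte-identical across
reruns with the same seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_digest(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    command: str
    tool_version: str
    seed: int | None = None
    config_digest: str | None = None
    input_digests: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "tool_version": self.tool_version,
            "seed": self.seed,
            "config_digest": self.config_digest,
            "input_digests": dict(self.input_digests),
        }


def build_manifest(
    command: str,
    tool_version: str,
    inputs: dict[str, str | Path],
    seed: int | None = None,
    config: dict | None = None,
) -> RunManifest:
    return RunManifest(
        command=command,
        tool_version=tool_version,
        seed=seed,
        config_digest=config_digest(config) if config is not None else None,
        input_digests={name: file_digest(p) for name, p in inputs.items()},
    )
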