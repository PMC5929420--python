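"""Run manifests: enough provenance to reproduce any CLI output."""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .config import PyTargConfig


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """What was run, on what inputs, with which constants."""

    command: str
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    tool_version: str = ""
    timestamp: str = ""

    @classmethod
    def create(
        cls,
        command: str,
        config: PyTargConfig,
        inputs: list[str | Path],
    ) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config=config.to_dict(),
            input_digests={str(p): _sha256(Path(p)) for p in inputs if p},
            tool_version=__version__,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def write(self, out_path: str | Path) -> Path:
        """Write next to an output file as ``<output>.manifest.json``."""
        target = Path(str(out_path) + ".manifest.json")
        target.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return target
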