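"""Run manifests: the reproducibility record written next to outputs."""

from __future__ import annotations

import datetime
import json
import os
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__


@dataclass
class RunManifest:
    """Seed, spec snapshot, and I/O paths of one command invocation.

    Re-running with the recorded seed and spec reproduces all
    deterministic outputs bit-identically.
    """

    stage: str
    seed: int | None
    spec: dict = field(default_factory=dict)
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    timestamp: str = ""
    version: str = __version__

    def write(self, path: str | Path) -> None:
        """Atomic write (temp file + rename) so partial manifests never appear."""
        path = Path(path)
        data = asdict(self)
        data["timestamp"] = data["timestamp"] or datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat(timespec="seconds")
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                json.dump(data, fh, indent=2, sort_keys=True)
                fh.write("\n")
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
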