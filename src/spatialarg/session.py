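"""Local session store for the command-line interface.

A session is a plain directory holding one ``.trees`` file per named
entry plus a JSON index recording where each entry came from and which
operations produced it — enough to reconstruct the full operation chain.
No daemon, no lock files; everything is inspectable with a text editor.
"""

from __future__ import annotations

import datetime
import json
import os
from typing import Dict, List, Optional

from .errors import ValidationError
from .model import SpatialARG
from .ts_io import load_tree_sequence, save_tree_sequence

INDEX_NAME = "index.json"


class Session:
    def __init__(self, directory: str):
        self.directory = os.path.abspath(directory)
        os.makedirs(self.directory, exist_ok=True)
        self.index_path = os.path.join(self.directory, INDEX_NAME)
        if os.path.exists(self.index_path):
            with open(self.index_path) as f:
                self.index: Dict[str, dict] = json.load(f)
        else:
            self.index = {}

    def _write_index(self) -> None:
        with open(self.index_path, "w") as f:
            json.dump(self.index, f, indent=2, sort_keys=True)
            f.write("\n")

    def path_for(self, name: str) -> str:
        return os.path.join(self.directory, f"{name}.trees")

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def names(self) -> List[str]:
        return sorted(self.index)

    def entry(self, name: str) -> dict:
        if name not in self.index:
            raise ValidationError(
                f"no session entry named {name!r}; available: {self.names()}"
            )
        return self.index[name]

    def add(
        self,
        name: str,
        arg: SpatialARG,
        source: str,
        operations: Optional[List[dict]] = None,
        force: bool = False,
    ) -> str:
        if not name or "/" in name or name.startswith("."):
            raise ValidationError(f"invalid entry name {name!r}")
        if name in self.index and not force:
            raise ValidationError(
                f"session entry {name!r} already exists (use --force to replace)"
            )
        path = self.path_for(name)
        save_tree_sequence(arg, path, compressed=False)
        self.index[name] = {
            "file": os.path.basename(path),
            "source": source,
            "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "operations": operations or [],
        }
        self._write_index()
        return path

    def load(self, name: str) -> SpatialARG:
        self.entry(name)
        return load_tree_sequence(self.path_for(name))
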