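"""Regenerate src/cnakit/_checksums.py from the packaged data files."""

import hashlib
from pathlib import Path

pkg = Path(__file__).resolve().parents[1] / "src" / "cnakit"
lines = [
    '"""sha256 digests of the packaged data fixtures (generated file)."""',
    "",
    "CHECKSUMS = {",
]
for path in sorted((pkg / "data").iterdir()):
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    lines.append(f'    "{path.name}": "{digest}",')
lines.append("}")
(pkg / "_checksums.py").write_text("\n".join(lines) + "\n")
print("wrote", pkg / "_checksums.py")
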