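"""Regenerate the golden report files under tests/data/golden/.

Run from the repository root after an intentional behavior change:

    python scripts/make_golden.py
"""

import shutil
import sys
import tempfile
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "tests"))

from golden_pipeline import GOLDEN_FILES, run_golden_pipeline  # noqa: E402


def main() -> None:
    golden_dir = ROOT / "tests" / "data" / "golden"
    golden_dir.mkdir(parents=True, exist_ok=True)
    with tempfile.TemporaryDirectory() as tmp:
        outdir = run_golden_pipeline(Path(tmp))
        for name in GOLDEN_FILES:
            shutil.copyfile(outdir / name, golden_dir / name)
            print(f"wrote {golden_dir / name}")


if __name__ == "__main__":
    main()
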