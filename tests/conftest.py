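import sys
from pathlib import Path

# allow cross-module imports of shared oracle helpers (e.g. the brute-force
# threshold checks in test_thresholding) when tests run from any rootdir
sys.path.insert(0, str(Path(__file__).parent))
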