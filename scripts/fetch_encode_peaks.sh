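#!/usr/bin/env bash
# Optional helper: download the three EGR1 IDR narrowPeak sets (GM12878,
# H1-hESC, K562) used by the consensus-peak count check, into scratch/encode/.
# Requires network access; the test that consumes these files skips when
# they are absent.
set -euo pipefail
dir="$(dirname "$0")/../scratch/encode"
mkdir -p "$dir"
for acc in ENCFF002CIV ENCFF002CGW ENCFF002CLV; do
    out="$dir/$acc.bed"
    if [ ! -s "$out" ]; then
        curl -L "https://www.encodeproject.org/files/$acc/@@download/$acc.bed.gz" \
            | gunzip -c > "$out"
    fi
    echo "$acc: $(wc -l < "$out") peaks"
done
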