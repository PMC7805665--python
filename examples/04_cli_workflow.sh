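#!/usr/bin/env bash
# Shell workflow mirroring examples/03 with the `ctseg` command:
# simulate -> fingerprint -> train one fold -> predict -> evaluate.
set -euo pipefail

WORK=$(mktemp -d)
echo "working in $WORK"

ctseg simulate --n 6 --out "$WORK/data" --seed 4 --grid 32

ctseg fingerprint --manifest "$WORK/data/manifest.json" \
    --out "$WORK/fingerprint.json"

ctseg plan --task kidney --resolution full

cat > "$WORK/run.yaml" <<EOF
network:
  base_features: 8
  levels_per_axis: [3, 3, 3]
  ag_levels: 2
  dsv_levels: 3
training:
  lr: 0.001
  max_iterations: 60
  max_epochs: 1000000
EOF

ctseg train --manifest "$WORK/data/manifest.json" --out "$WORK/run" \
    --config "$WORK/run.yaml" --fold 0 --folds 3 --seed 0 \
    --patch-size 16 16 16

ctseg predict --checkpoint "$WORK/run/fold0.npz" \
    --image "$WORK/data/phantom_000_image.nii.gz" \
    --fingerprint "$WORK/run/fingerprint.json" \
    --out "$WORK/pred.nii.gz" --patch-size 16 16 16

ctseg evaluate --pred "$WORK/pred.nii.gz" \
    --truth "$WORK/data/phantom_000_mask.nii.gz" \
    --out "$WORK/metrics.csv"

ctseg export-maps --checkpoint "$WORK/run/fold0.npz" \
    --image "$WORK/data/phantom_000_image.nii.gz" \
    --fingerprint "$WORK/run/fingerprint.json" \
    --out "$WORK/maps" --patch-size 16 16 16

ls "$WORK/maps"
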