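#!/usr/bin/env bash
# The same study as a shell pipeline: simulate -> features -> pretrain ->
# probe -> finetune -> aggregate.  Every artifact embeds the seed and config
# digest, so the chain is exactly repeatable.
set -euo pipefail
mkdir -p out

wearssl simulate --seed 7 --out out/data.h5 --truth out/truth.json
wearssl features --seed 7 --data out/data.h5 --out out/features.csv --stats out/stats.json
wearssl pretrain --seed 7 --data out/data.h5 --features out/features.csv \
    --out out/ckpt.npz --log out/train.jsonl
wearssl probe --seed 7 --data out/data.h5 --checkpoint out/ckpt.npz \
    --probe linear --out out/probe_linear.json
wearssl probe --seed 7 --data out/data.h5 --checkpoint out/ckpt.npz \
    --probe knn --k 10 --out out/probe_knn.json
wearssl finetune --seed 7 --data out/data.h5 --checkpoint out/ckpt.npz \
    --fraction 0.1 --out out/finetune_10pct.json
wearssl report --inputs out/probe_linear.json out/probe_knn.json \
    out/finetune_10pct.json --out out/summary.csv
cat out/summary.csv
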