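# Full-scale pretraining configuration (the original CLAPS training setup).
# Any key may be overridden on the command line; unknown keys are rejected.

strategy: roulette        # positive-sample masking: roulette | top | random
ratio: 0.25               # fraction of characters masked per positive sample
batch_size: 1500          # molecules per contrastive minibatch (2N projections)
projection_hidden: 2048   # contrastive projection head, hidden width
projection_out: 512       # contrastive projection head, output width
lr_pretrain: 1.0e-3       # Adam step size, pretraining
lr_finetune: 1.0e-4       # Adam step size, fine-tuning
dropout: 0.2              # after attention and feed-forward sublayers
epochs_pretrain: 30
pss_heads: 3              # heads in the positive-sample-selection network
pss_layers: 2
encoder_layers: 3
encoder_heads: 4
temperature: 0.1          # NT-Xent temperature (not fixed by the method;
                          # exposed deliberately)
max_len: 220              # fixed sequence length C; longer strings error
d: 128                    # character embedding / model dimension
predictor_dims: [4096, 512, 64]
epochs_finetune: 100
patience: 10
pooling: mean             # mean | sum over non-pad positions
weight_decay: 0.0
weight_ema: 0.9           # Polyak averaging of fine-tune weights (0 = off)
roulette_probs: attention # attention | occurrence
freeze_encoder: false
seed: 7
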