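# Non-service uses of military vocabulary. Each entry strictly contains a
# military term; matches of military terms inside these spans carry no
# evidence of service and are suppressed.
salvation army
church army
army surplus
army and navy stores
barmy army
toy soldier
toy soldiers
navy blue
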