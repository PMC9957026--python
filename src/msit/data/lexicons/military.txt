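# Default military-service lexicon (one phrase per line, '#' = comment).
# Seeded with service-branch names, rank words and service phrases; the
# shipped list is a configurable data artifact, not code — extend or replace
# it with --lexicon-dir / load_lexicon for other settings.
veteran
veterans
army
navy
royal navy
air force
royal air force
raf
marines
royal marines
armed forces
the armed forces
served in the forces
served in the army
served in the navy
served in the air force
served in the military
military service
national service
ex serviceman
ex servicewoman
ex forces
soldier
sailor
airman
infantry
regiment
battalion
platoon
sergeant
corporal
lance corporal
tour of duty
demobbed
enlisted
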