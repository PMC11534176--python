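# Built-in exemplar firearm lexicon: term<TAB>category
# category is one of broad, gun_only, shooting
firearm	broad
gsw	broad
gunpoint	broad
gun	gun_only
gunshot	shooting
shot	shooting
shooting	shooting
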