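smn_1	cerebrum
smn_2	cerebrum
smn_3	cerebrum
smn_4	cerebrum
smn_5	cerebrum
dmn_1	cerebrum
dmn_2	cerebrum
dmn_3	cerebrum
dmn_4	cerebrum
dmn_5	cerebrum
vis_1	cerebrum
vis_2	cerebrum
vis_3	cerebrum
vis_4	cerebrum
vis_5	cerebrum
aud_1	cerebrum
aud_2	cerebrum
aud_3	cerebrum
aud_4	cerebrum
aud_5	cerebrum
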