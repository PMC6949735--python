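ingredient_id
mol01
mol02
mol03
mol04
mol05
mol06
mol07
mol08
mol09
mol10
mol11
mol12
mol13
mol14
mol15
mol16
mol17
mol18
mol19
mol20
mol21
mol22
mol23
mol24
mol25
mol26
mol27
mol28
mol29
mol30
mol31
mol32
mol33
mol34
mol35
mol36
mol37
mol38
mol39
mol40
mol41
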