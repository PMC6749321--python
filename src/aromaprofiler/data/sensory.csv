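variety,age_class,notes
Malvasia,young,almond|banana|citrus|cocoa|floral|tobacco|wood
Malvasia,old,almond|caramel|dried fruits|spice|tobacco|toast|vanilla|wood
Bual,young,almond|banana|cocoa|floral|tea
Bual,old,almond|caramel|dried fruits|spice|tea|toast|wood
Sercial,young,citrus|honey|mushroom|waxy
Sercial,old,dried fruits|honey|spice|toast|vanilla|wood
Verdelho,young,banana|floral|honey|mushroom|spice
Verdelho,old,dried fruits|ethereal|honey|spice|toast|wood
Tinta Negra,young,citrus|ripe fruit|tea|wood
Tinta Negra,old,caramel|dried fruits|spice|tea|toast|wood
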