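word	role	synonyms
boy	subject	son|brother
girl	subject	daughter|sister
mother	subject	woman|lady|mom
cookie	object	cookies|biscuit
jar	object
stool	object	chair|ladder
sink	object	basin
water	object
plate	object	dish|dishes
cup	object	cups
curtain	object	curtains|drape|drapes
window	object
cupboard	object	cabinet|shelf
faucet	object	tap
counter	object	countertop
kitchen	place
garden	place	yard|outside
steal	action	stealing|take|taking|sneak|sneaking
fall	action	falling|tip|tipping|topple|toppling|wobble|wobbling
overflow	action	overflowing|run|running|spill|spilling
wash	action	washing|dry|drying|clean|cleaning
reach	action	reaching|grab|grabbing|hand|handing
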