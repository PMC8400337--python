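pattern,food_group,is_prebiotic,is_probiotic
garlic,vegetables,1,0
onion,vegetables,1,0
banana,fruit,1,0
oat,grains,1,0
oatmeal,grains,1,0
apple,fruit,1,0
applesauce,fruit,1,0
pear,fruit,1,0
flaxseed,grains,1,0
flax,grains,1,0
wheat bran,grains,1,0
whole grain,grains,1,0
whole wheat,grains,1,0
broccoli,vegetables,1,0
cauliflower,vegetables,1,0
cabbage,vegetables,1,0
kale,vegetables,1,0
brussels sprout,vegetables,1,0
bok choy,vegetables,1,0
legume,grains,1,0
bean,grains,1,0
lentil,grains,1,0
chickpea,grains,1,0
pea,vegetables,1,0
honey,confections_desserts,1,0
coconut,fruit,1,0
berry,fruit,1,0
berries,fruit,1,0
blueberry,fruit,1,0
strawberry,fruit,1,0
raspberry,fruit,1,0
blackberry,fruit,1,0
corn,grains,1,0
cornmeal,grains,1,0
popcorn,grains,1,0
yoghurt,dairy,0,1
yogurt,dairy,0,1
kefir,dairy,0,1
cheese,dairy,0,1
pickle,vegetables,0,1
pickled,vegetables,0,1
sauerkraut,vegetables,0,1
kimchi,vegetables,0,1
tempeh,grains,0,1
miso,grains,0,1
sourdough,grains,0,1
fermented,,0,1
carrot,vegetables,0,0
avocado,fruit,0,0
sweet potato,vegetables,0,0
potato,vegetables,0,0
squash,vegetables,0,0
pumpkin,vegetables,0,0
zucchini,vegetables,0,0
spinach,vegetables,0,0
green bean,vegetables,0,0
celery,vegetables,0,0
cucumber,vegetables,0,0
tomato,vegetables,0,0
beet,vegetables,0,0
parsnip,vegetables,0,0
mango,fruit,0,0
peach,fruit,0,0
plum,fruit,0,0
melon,fruit,0,0
watermelon,fruit,0,0
orange,fruit,0,0
grape,fruit,0,0
kiwi,fruit,0,0
prune,fruit,0,0
apricot,fruit,0,0
cherry,fruit,0,0
rice,grains,0,0
rice cereal,grains,0,0
baby cereal,grains,0,0
barley,grains,0,0
quinoa,grains,0,0
wheat,grains,0,0
bread,grains,0,0
pasta,grains,0,0
toast,grains,0,0
cracker,grains,0,0
rusk,grains,0,0
chicken,meat,0,0
beef,meat,0,0
pork,meat,0,0
turkey,meat,0,0
lamb,meat,0,0
fish,meat,0,0
salmon,meat,0,0
egg,meat,0,0
milk,dairy,0,0
cream cheese,dairy,0,0
butter,dairy,0,0
olive oil,oils,0,0
canola oil,oils,0,0
sunflower oil,oils,0,0
oil,oils,0,0
cookie,confections_desserts,0,0
biscuit,confections_desserts,0,0
cake,confections_desserts,0,0
pudding,confections_desserts,0,0
maple syrup,confections_desserts,0,0
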